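"""In vitro phantom: simulate a BURST acquisition of a gas-vesicle well and
quantify its signal-to-background ratio.

Builds a scene with one circular sample well of gas-vesicle-expressing cells
in a speckled agarose background, runs the 8-frame L22-14vX collapse
schedule, reconstructs BURST (first minus last collapsing frame) and reports
SBR and its dB value. Higher gas-vesicle amplitude means brighter wells and
larger SBR.
"""

import numpy as np

from gvscan.config import build_schedule
from gvscan.quantify import sbr, to_db
from gvscan.reconstruct import burst_invitro
from gvscan.screening import disk_roi
from gvscan.simulate import SceneTruth, simulate_acquisition

cfg = build_schedule("L22-14vX in vitro")
shape = (64, 48)
well = disk_roi(shape, (32, 24), 8)
background_roi = disk_roi(shape, (32, 8), 5)

for amplitude in (0.5, 2.0, 8.0):
    scene = SceneTruth(
        gv_map=np.where(well, amplitude, 0.0),
        background_map=np.ones(shape),
        speckle_scale=1.0,
        noise_sd=0.02,
        seed=11,
    )
    stack = simulate_acquisition(cfg, scene)
    image = burst_invitro(stack).pixels + 1.0  # shift onto a positive baseline
    ratio = sbr(image, well, background_roi)
    print(f"gv amplitude {amplitude:4.1f}  ->  SBR {ratio:6.2f}  ({to_db(ratio):5.1f} dB)")

print("\nSBR rises monotonically with expression level; dB is 20*log10(SBR).")
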