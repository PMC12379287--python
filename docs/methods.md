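# Methods

## Signal model and simulator

The simulator produces beamformed envelope frames directly; RF-domain
propagation and beamforming are out of scope because they are
hardware-specific and contribute nothing testable to the analysis that
follows. A frame `f` at pixel `p` is

    I_f(p) = background(p) · S(p) + gv(p) · c_f + ε_f(p),  clipped at 0

* `S` — one multiplicative speckle realization per acquisition, held fixed
  across frames. It is the squared magnitude of a smoothed complex circular
  Gaussian field, normalized to unit mean: fully developed speckle has an
  exponential (right-skewed) intensity law, and the Gaussian smoothing
  length (`speckle_scale`, pixels, default 1.0) sets the correlation
  length. Keeping `S` fixed across frames is what makes collapse
  differencing work — the difference of two static frames is exactly zero.
* `gv` — the gas-vesicle contrast amplitude map (arbitrary linear units).
* `c_f` — the per-frame multiplier. Low-voltage frames carry a small
  pre-collapse visibility `c_low = 0.1·c_1` (pre-collapse linear scattering
  is real but weak; the exact magnitude is a free parameter). Collapsing
  frames follow the collapse profile: for GI (BURST\*) modes the default is
  `(0.6, 1.0, 0.5, 0.25, 0.1, 0.05, 0.0)` over 7 frames — a rise from the
  first to the second collapsing frame, then decay to zero — and for the in
  vitro (BURST) mode a geometric decay from 1 with the last frame pinned to
  0. Only the orderings are physically constrained; the magnitudes are
  model parameters.
* `ε` — i.i.d. Gaussian noise with sd `noise_sd`. The 50-accumulation
  frame averaging used in vitro is modeled as a `√50` noise-sd reduction
  rather than 50 explicit sub-frames; the two are equivalent in expectation
  and the former is 50× cheaper.
* Motion ("breathing") is a rigid (axial, lateral) translation of the
  affected frame plus partial replacement of its speckle by a fresh
  realization, weighted by a `decorrelation` fraction in [0, 1]. The
  affected frame's motion flag is set in the output stack; flags are ground
  truth for detector tests and are never consumed by reconstruction.

Every simulator output is a pure function of its parameters and an integer
seed (`numpy.random.default_rng`); scan- and ensemble-level seeds are
spawned from a master seed with `SeedSequence`, as is the per-stage fan-out
in the pipeline orchestrator.

The other generators mirror the statistical structure the analysis assumes:
Hill-curve titrations with multiplicative CV-scaled replicate noise clipped
at zero; patch plates as disks on a linearly drifting background with an
adjacent background ROI per patch; flow samples as log-normal FSC/SSC
scatter with bimodal mCherry and a two-component log-normal GFP mixture.

What the simulator does **not** emulate: depth-dependent attenuation and
time-gain compensation, transducer point-spread functions, nonlinear (xAM)
propagation, deformable tissue motion, plate-image vignetting beyond a
linear gradient, and fluorescence spillover between channels. Passing tests
therefore demonstrate the correctness of the analysis pipeline under its
own stated model, not instrument-level fidelity.

## Reconstruction and motion screening

BURST is the first minus the last collapsing frame; BURST\* is the second
minus the first; B-mode is the first collapsing frame. Difference images
are signed and stay signed through quantification — the total-signal sum
includes negative pixels by default (a clip-at-zero variant exists for
sensitivity analysis) — and negatives are only floored at display time.

Motion screening is an automated surrogate for by-eye exclusion: the score
is `1 − Pearson r` between the two frames the active reconstruction
differences, optionally restricted to a background band; an acquisition is
excluded when the score exceeds a threshold (default 0.5 — a free
parameter, configurable) or when it is on a user-supplied manual exclusion
list, which remains authoritative. Constant frames make the correlation
undefined; the score is reported as 0 with a warning.

## Assembly

Transverse planes are lateral concatenations of the across-body
acquisitions at stage spacing. When the stage step differs from the image
width, the default policy crops each block to the step width centered on
the beam axis; an overlap-averaging policy is available. Excluded
acquisitions are zeroed only in the BURST\* channel — B-mode keeps the
anatomy everywhere, matching the display convention of a full B-mode with
holes in the overlay. Volumes carry their anisotropic voxel spacing
(longitudinal step ≫ in-plane pixel) in metadata. Ex vivo series use signed
length coordinates, positive toward the rectum, zero at the cecum landmark.
Missing plane ROIs degrade to an all-background plane with a warning;
a strict mode rejects instead.

## Quantification

Depth windows are half-open `[lo, hi)` in mm with boundaries converted to
voxel indices by rounding down. The comparative-display constants table is
`{BURST: L22-14v (A=3, B=1), L22-14vX (A=2, B=0.5); xAM: L22-14v (A=2,
B=0.5), L22-14vX (A=2, B=0.4)}`; limits are computed once per compared set,
never per image, which is what makes the display scale-invariant. The
overlay threshold is a free parameter; the default policy uses the 97.5th
percentile of the BURST\* pixel distribution as a noise floor, with a
fixed-value alternative.

## Dose-response fitting

The four-parameter Hill model is fitted by trust-region least squares from
a fixed multi-start grid: 7 log-spaced K values spanning the positive
concentrations × n ∈ {0.5, 1, 2, 4}, best residual wins, ties broken by the
smaller K — making the fit deterministic for a given data set. K and n are
parameterized on the log scale with wide bounds. Flat responses are flagged
unidentifiable (K reported as not determined, fold change 1) rather than
returning an arbitrary K. The maximal fold change is defined on condition
means with the zero-dose mean as baseline — matching how fold-change
annotations span the uninduced and peak-dose points on titration plots —
and the fitted variant `ymax/y0` is reported alongside. The detection-limit
criterion is the blank mean plus three blank standard deviations, recorded
in the output; the rule itself is a package choice since only detection
outcomes, not criteria, are conventionally reported.

## Screening

Patch opacity is the mean patch-ROI intensity minus the mean of an adjacent
background ROI (correcting plate-illumination nonuniformity), normalized so
the parent strain at 0 mM inducer / 30 °C maps to 0 and at 1 mM / 30 °C
maps to 1. Anchors are computed per experiment batch (per-plate anchoring
is possible by passing per-plate anchor objects). The hit rule is a
quantitative surrogate for a visual pick: a candidate is a hit when its
1 mM corrected opacity exceeds its 0 mM value by `0.25·(a1 − a0)`; ranking
is by induced relative opacity descending with the lower uninduced value
breaking ties. Both the statistic and the ranking are invariant to affine
intensity transforms applied to image and anchors together.

## Assays

CFU/g = colonies / (plated volume × overall dilution × homogenate density),
with a one-colony limit of detection reported alongside zero counts. Flow
gating uses rectangular FSC/SSC ranges plus an mCherry (Y2) threshold —
gate geometry is a config input with log-space-rectangle defaults, since
instrument-specific gates do not transfer. The GFP geometric mean floors
nonpositive B1 values at 1.0 channel unit (the scale of the channel
threshold) before logs; the GFP-positive fraction counts events strictly
above B1 = 1000 among gated events. Freedman–Diaconis binning uses width
`2·IQR·n^(−1/3)` with the count floored at 100 and a 100-bin fallback for
degenerate (zero-IQR or zero-range) data. Thiosulfate quantification
normalizes the thiosulfate peak area by the phosphate internal-standard
area, maps normalized area to concentration through an ordinary
least-squares line over the external standards (not forced through the
origin), scales by the dilution factor, averages technical replicates per
sample, and flags samples outside the standard range as extrapolated.

## Problem sizes and numerical choices

Tests and the acceptance script run on reduced geometries chosen to keep
the full suite fast while exercising every code path: 16×12 to 24×48-pixel
frames, 3×6 to 3×10 scan grids (the planner itself is verified at the full
3×80 = 240-position protocol), 200-seed Monte-Carlo ensembles for the null
and Hill-recovery checks, and 4 000–20 000-event flow samples. Statistical
assertions use sampling-error-based bounds (3–4 standard errors) rather
than fixed tolerances wherever the quantity is stochastic; exact identities
(frame differencing, Fubini, dB, anchors) are asserted to 1e-12 or
equality. Envelope intensities are clipped at zero after noise addition;
with the default background level the clip probability is negligible
(≈20 σ), so it does not bias the null tests.

## Known limitations

* The collapse-profile magnitudes, pre-collapse visibility, motion model
  and overlay threshold are model parameters, not measured constants; any
  quantitative claim tied to their values is a claim about the simulator.
* The Hill fit assumes homoscedastic residuals; replicate-variance
  weighting is not implemented.
* The stitching policies (crop / average) bracket, but do not resolve, how
  overlapping lateral blocks should be combined when the stage step is
  smaller than the image width.
* FCS file reading is not included; flow events enter as tables.
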