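"""Biosensor titration: simulate a thiosulfate dose-response and fit the
Hill model.

Generates replicate SBR measurements across a concentration ladder from a
known Hill curve plus 10% multiplicative noise, fits the four-parameter
model y(c) = y0 + (ymax - y0) * c^n / (K^n + c^n), and reports the
half-maximum constant K, cooperativity n, and the maximal fold change (max
condition mean over the zero-dose mean).
"""

from gvscan.dose_response import DoseResponseData, fit_hill, max_fold_change
from gvscan.simulate import simulate_dose_response

true = dict(y0=1.5, ymax=75.0, half_max_conc=48.0, hill_n=1.6)
table = simulate_dose_response(
    **true, conc_list=[0, 5, 10, 25, 50, 100, 250, 1000], n_reps=4,
    noise_cv=0.10, seed=21,
)
data = DoseResponseData.from_table(table)
fit = fit_hill(data)

print(f"true parameters:  y0={true['y0']}, ymax={true['ymax']}, "
      f"K={true['half_max_conc']} uM, n={true['hill_n']}")
print(f"fitted:           y0={fit.y0:.2f}, ymax={fit.ymax:.1f}, "
      f"K={fit.K:.1f} uM, n={fit.n:.2f}")
print(f"fold change:      empirical {max_fold_change(data):.1f}, "
      f"fitted ymax/y0 {fit.fold_change:.1f}")
print(f"residual RMS:     {fit.residual_rms:.2f}")
print("\nK is the concentration at half-maximal response; the fold change is")
print("how much brighter the fully induced sensor is than its baseline.")
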