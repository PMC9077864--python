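"""Decompose the relative dose uncertainty of a calibrated measurement.

Fits the calibration curve D = b*netOD + c*netOD^n on noisy synthetic
points, then splits the relative uncertainty of a converted dose into its
experimental (scan-noise) and fit (parameter-uncertainty) parts, combined
in quadrature.
"""

import numpy as np

from clodscan import fit_calibration, total_uncertainty

rng = np.random.default_rng(11)
netods = np.repeat([0.0, 0.03, 0.08, 0.16, 0.22, 0.31], 3)
doses_gy = 0.9 * netods + 0.5 * netods**2 + rng.normal(0, 0.004, netods.size)
doses_gy[netods == 0] = 0.0

fit = fit_calibration(netods, doses_gy)
print(
    f"calibration fit: b={fit.lin_coeff:.3f} Gy/netOD  c={fit.pow_coeff:.3f}"
    f"  n={fit.exponent:.3f}  sigma_b={fit.sigma_lin:.4f}  sigma_c={fit.sigma_pow:.4f}"
)
print("\n netOD   D_fit(cGy)   sigma_exp%  sigma_fit%  sigma_tot%")
for netod in (0.05, 0.10, 0.20, 0.30):
    budget = total_uncertainty(fit, netod, sigma_netod=0.003)
    print(
        f"  {netod:.2f}   {budget.at_dose_gy * 100:8.1f}"
        f"     {budget.sigma_exp_pct:6.1f}      {budget.sigma_fit_pct:6.1f}"
        f"      {budget.sigma_tot_pct:6.1f}"
    )
print(
    "\nThe experimental part propagates the netOD scan noise through the\n"
    "local slope of the curve; the fit part propagates the parameter SDs.\n"
    "Relative uncertainty is largest at low dose, where the signal is small."
)
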