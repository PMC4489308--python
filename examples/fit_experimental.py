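"""Fit a (synthetic) experimental curve to a predicted curve.

The experimental curve is fitted to the prediction — never the other
way around — with only a scale f and offset c, by an error-weighted
chi^2 and by a log-space chi^2 that balances small and wide angles.
Here the 'experimental' data are a planted transform of the prediction
plus noise, so the fit should recover f = 2.0 and c = 15 closely.
"""

import numpy as np

from solvaxs import ExperimentalCurve, ScatteringCurve, fit_chi2, fit_chi2log

rng = np.random.default_rng(0)
q = np.linspace(0.0, 0.6, 80)
I_calc = 1000.0 * np.exp(-(q * 12.0) ** 2 / 3.0) + 25.0
calc = ScatteringCurve(q=q, I=I_calc)

f_true, c_true = 2.0, 15.0
sigma = np.full(80, 3.0)
I_exp = (I_calc - c_true) / f_true + rng.normal(0.0, sigma)
exp = ExperimentalCurve(q=q, I=I_exp, sigma=sigma)

r = fit_chi2(calc, exp)
rlog = fit_chi2log(calc, exp)
print(f"chi^2 fit:     f = {r.f:.4f}, c = {r.c:.3f}, chi^2 = {r.chi2:.3f} (chi = {r.chi:.3f})")
print(f"chi^2_log fit: f = {rlog.f:.4f}, c = {rlog.c:.3f}, chi^2_log = {rlog.chi2log:.5f}")
print(
    "\nBoth metrics recover the planted scale/offset; chi^2 near f^2 = 4"
    "\ntimes unity per point would signal sigma-consistent residuals."
)
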