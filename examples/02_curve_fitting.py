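"""Weibull curve fitting on synthetic pseudo-individual-patient data.

Draws event times from a known Weibull law (the pooled-reference scale of
a progression-free-survival fit), censors administratively, estimates the
Kaplan-Meier curve, and refits the Weibull on the complementary-log-log
scale — demonstrating that the fitting pipeline recovers the generating
parameters.
"""

from mrcc_cea import WeibullParams, fit_weibull, generate_ipd, km_estimate

truth = WeibullParams(scale=0.2447073, shape=0.7914)
ipd = generate_ipd(truth, n=5000, censor_horizon=40.0, seed=7)
print(f"simulated {len(ipd)} patients, {int((~ipd.events).sum())} censored at 40 cycles")

points = km_estimate(ipd)
fit = fit_weibull(points)
p = fit.params
print(f"true scale/shape      : {truth.scale:.5f} / {truth.shape:.4f}")
print(f"recovered scale/shape : {p.scale:.5f} / {p.shape:.4f}")
print(f"adjusted R^2          : {fit.adj_r2:.4f}")
print(f"scale-shape correlation: {p.correlation:.3f}")
print(
    "\nThe estimates land within sampling error of the truth, the"
    "\nlinearised fit is near-perfect (R^2 ~ 1), and the scale and shape"
    "\nestimates are strongly anticorrelated — the same diagnostics"
    "\nreported for the trial curve fits the model consumes."
)
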