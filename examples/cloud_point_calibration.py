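"""Calibrate buffer interaction parameters from (synthetic) cloud points.

Generates a cloud-point-vs-ionic-strength series from the model itself with
cacodylate's known parameters plus 0.2 K Gaussian noise, then runs the
calibration pipeline: invert each cloud point to a well depth epsilon(I),
regress epsilon against sqrt(I), and read off eps0 (intercept) and the salt
coefficient a (slope).
"""

from patchyllps import (
    buffer_fixtures,
    fit_epsilon_series,
    fit_salt_coefficients,
    gen_cloud_point_series,
    hewl_model,
)

model = hewl_model()
truth = next(b for b in buffer_fixtures() if b.name == "cacodylate")

series = gen_cloud_point_series(
    model, truth, gamma=90.0, ionic_strengths=(0.1, 0.2, 0.3, 0.4, 0.5),
    noise_sd=0.2, seed=42,
)
print("I/M    T_cloud/K (noisy)   epsilon(I)/K inverted")
points = fit_epsilon_series(series, model)
for (ionic, t, _), p in zip(series.observations, points):
    print(f"{ionic:.1f}   {t:12.3f}       {p.eps:12.2f}")

fit = fit_salt_coefficients(points, name="cacodylate")
print(
    f"\nfitted eps0 = {fit.buffer.eps0:7.1f} +/- {fit.eps0_se:.1f} K   "
    f"(truth {truth.eps0:.0f})"
)
print(
    f"fitted a    = {fit.buffer.salt_coeff:7.1f} +/- {fit.salt_coeff_se:.1f} "
    f"K L^1/2 mol^-1/2 (truth {truth.salt_coeff:.0f})"
)
print(
    "\nEach cloud point pins the well depth at that salt level; the sqrt(I)"
    "\nregression separates the buffer's intrinsic attraction (eps0) from the"
    "\nsalting-out response (a). Errors of a few kelvin match the uncertainty"
    "\nscale reported for such fits."
)
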