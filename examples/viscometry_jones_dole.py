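"""Ostwald viscometry to Jones-Dole coefficients, and their link to eps0.

Reduces capillary flow times to viscosities (eta = eta0 * rho t / rho0 t0),
fits the Jones-Dole expansion eta/eta0 = 1 + A sqrt(c) + B c, and correlates
the packaged buffers' B coefficients with their fitted well depths.
"""

from patchyllps import (
    ViscositySeries,
    buffer_fixtures,
    jones_dole_fit,
    linear_correlation,
    viscosity_from_flow,
)

# phosphate-like raw flow-time series at 25 C (water: t0=100 s, 0.9970 g/cm3)
raw = ViscositySeries(
    points=(
        (0.02, 100.92, 0.9985),
        (0.04, 101.83, 1.0000),
        (0.06, 102.76, 1.0015),
        (0.08, 103.69, 1.0029),
        (0.10, 104.62, 1.0044),
    ),
    raw=True,
    reference=(100.0, 0.9970, 0.8900),
)
reduced = viscosity_from_flow(raw)
print("c/M     eta/mPa s   eta_rel")
for c, eta, rel in reduced:
    print(f"{c:.2f}   {eta:9.4f}   {rel:7.4f}")

fit = jones_dole_fit([(c, rel) for c, _, rel in reduced])
print(f"\nJones-Dole A = {fit.a:.3f} L^1/2 mol^-1/2, B = {fit.b:.3f} L/mol")

buffers = buffer_fixtures()
corr = linear_correlation([b.eps0 for b in buffers], [b.jones_dole_b for b in buffers])
print(
    f"across buffers: B vs eps0 slope = {corr.slope:.2e} L mol^-1 K^-1, "
    f"r = {corr.pearson_r:.2f}"
)
print(
    "\nA positive B marks a kosmotropic (water-structuring) buffer ion. Ions"
    "\nwith smaller B shed hydration water more easily, adsorb on the protein"
    "\nsurface, screen its charge and so deepen the effective protein-protein"
    "\nattraction eps0 - hence the negative trend of B against eps0."
)
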