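"""Physical constants and unit-bridge factors.

All energies in the package are carried as epsilon/k_B in kelvin; lengths in
nm; number densities in nm^-3; mass concentrations in mg/mL. These factors
centralize every conversion so derived quantities (B22 in mol mL/g^2, kD in
mL/g) are bit-reproducible.
"""

AVOGADRO = 6.02214076e23
"""Avogadro constant, mol^-1 (exact, SI 2019)."""

BOLTZMANN_J_PER_K = 1.380649e-23
"""Boltzmann constant, J/K (exact, SI 2019). Used only in Stokes-Einstein."""

NM3_PER_LITER = 1.0e24
"""nm^3 in one litre."""

ML_PER_NM3 = 1.0e-21
"""mL in one nm^3."""

THERMAL_WAVELENGTH_NM = 1.0
"""de Broglie wavelength entering the ideal free energy, fixed to 1 nm.

It shifts the chemical potential by a state-independent constant and cancels
identically in every coexistence condition; it is a convention, not a knob.
"""
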