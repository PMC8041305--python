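"""Reduction of light-scattering and viscometry measurements to parameters.

Covers the standard bench math: Stokes-Einstein between diffusion coefficient
and hydrodynamic radius; the interaction diffusion coefficient kD from the
concentration dependence D = D0 (1 + kD*gamma); toluene-referenced static
scattering to Kc/R and the Debye-plot fit Kc/R = 1/Mw + 2*B22*c; capillary
(Ostwald) viscometry eta = eta0 * (rho t)/(rho0 t0); and the Jones-Dole
expansion eta/eta0 = 1 + A*sqrt(c) + B*c.

All fits are linear least squares via statsmodels; reported units follow the
conventions of protein solution work: kD in mL/g, B22 in mol mL/g^2, the
Jones-Dole B in L/mol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .constants import AVOGADRO, BOLTZMANN_J_PER_K

__all__ = [
    "DLSSeries",
    "SLSConfig",
    "SLSSeries",
    "ViscositySeries",
    "KDFitResult",
    "DebyeFitResult",
    "JonesDoleFitResult",
    "stokes_einstein_diffusion",
    "stokes_einstein_radius",
    "fit_interaction_diffusion",
    "optical_constant",
    "reduce_sls",
    "debye_fit",
    "viscosity_from_flow",
    "jones_dole_fit",
    "concentration_from_absorbance",
]


@dataclass(frozen=True)
class DLSSeries:
    """Collective diffusion coefficient vs protein mass concentration.

    ``points`` are (gamma mg/mL, D m^2/s) pairs at one temperature in one
    solvent (viscosity in mPa s).
    """

    points: tuple[tuple[float, float], ...]
    solvent_viscosity: float = 0.8900
    temperature: float = 298.15
    meta: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        pts = tuple((float(g), float(d)) for g, d in self.points)
        object.__setattr__(self, "points", pts)
        gammas = [p[0] for p in pts]
        if any(g <= 0 for g in gammas) or len(set(gammas)) != len(gammas):
            raise ValueError("gammas must be positive and distinct")
        if any(p[1] <= 0 for p in pts):
            raise ValueError("diffusion coefficients must be > 0")


@dataclass(frozen=True)
class SLSConfig:
    """Optics of the static-scattering setup (90 degrees, single angle)."""

    wavelength: float = 632.8          # nm
    refractive_index: float = 1.332    # aqueous buffer at 632.8 nm
    dn_dc: float = 0.185               # mL/g, globular proteins
    rayleigh_toluene: float = 14.0e-6  # cm^-1


@dataclass(frozen=True)
class SLSSeries:
    """Static-scattering series: either raw mean count rates or Kc/R values.

    ``points`` are (conc g/mL, mean count rate counts/s) when ``raw`` is
    True, else (conc g/mL, Kc/R mol/g). Count rates are normalised by
    ``laser_intensity`` and referenced to ``toluene_count_rate``.
    """

    points: tuple[tuple[float, float], ...]
    raw: bool = True
    laser_intensity: float = 1.0
    toluene_count_rate: float | None = None
    config: SLSConfig = SLSConfig()
    meta: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(v)) for c, v in self.points)
        object.__setattr__(self, "points", pts)
        if any(c <= 0 for c, _ in pts):
            raise ValueError("concentrations must be > 0 (g/mL)")


@dataclass(frozen=True)
class ViscositySeries:
    """Relative viscosities (or raw flow times) vs solute concentration.

    ``points`` are (conc mol/L, eta_rel) when ``raw`` is False, else
    (conc mol/L, flow time s, mass density g/cm^3) with ``reference`` the
    water values (flow time s, density g/cm^3, viscosity mPa s).
    """

    points: tuple[tuple, ...]
    raw: bool = False
    reference: tuple[float, float, float] | None = None
    meta: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        pts = tuple(tuple(float(v) for v in p) for p in self.points)
        object.__setattr__(self, "points", pts)
        if any(p[0] < 0 for p in pts):
            raise ValueError("concentrations must be >= 0")
        if not self.raw and any(p[1] <= 0 for p in pts):
            raise ValueError("relative viscosities must be > 0")
        if self.raw and self.reference is None:
            raise ValueError("raw flow-time series needs a water reference")


@dataclass(frozen=True)
class KDFitResult:
    d0: float       # m^2/s
    kd: float       # mL/g
    d0_se: float
    kd_se: float
    n_points: int
    window: tuple[float, float]  # mg/mL


@dataclass(frozen=True)
class DebyeFitResult:
    mw: float | None  # g/mol; None when the intercept is non-positive
    b22: float        # mol mL / g^2
    mw_se: float | None
    b22_se: float
    n_points: int
    window: tuple[float, float]  # g/mL
    intercept: float             # mol/g


@dataclass(frozen=True)
class JonesDoleFitResult:
    a: float   # L^(1/2) mol^(-1/2)
    b: float   # L/mol
    a_se: float
    b_se: float
    a_fixed: bool


def stokes_einstein_diffusion(
    radius: float, temperature: float, solvent_viscosity: float
) -> float:
    """D = k_B T / (6 pi eta0 R_h); radius in nm, viscosity in mPa s -> m^2/s."""
    if radius <= 0 or temperature <= 0 or solvent_viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must be > 0")
    return BOLTZMANN_J_PER_K * temperature / (
        6 * math.pi * solvent_viscosity * 1e-3 * radius * 1e-9
    )


def stokes_einstein_radius(
    diffusion: float, temperature: float, solvent_viscosity: float
) -> float:
    """Inverse of :func:`stokes_einstein_diffusion`: m^2/s -> nm."""
    if diffusion <= 0 or temperature <= 0 or solvent_viscosity <= 0:
        raise ValueError("diffusion, temperature and viscosity must be > 0")
    return BOLTZMANN_J_PER_K * temperature / (
        6 * math.pi * solvent_viscosity * 1e-3 * diffusion
    ) * 1e9


def fit_interaction_diffusion(
    series: DLSSeries, window: tuple[float, float] | None = None
) -> KDFitResult:
    """Fit D = D0 (1 + kD * gamma) in the semidilute window.

    ``window`` restricts the concentrations used (mg/mL bounds, inclusive);
    default uses every supplied point. kD is reported in mL/g (gamma is
    converted to g/mL inside the fit), with the standard error from the
    delta method on the slope/intercept ratio.
    """
    pts = series.points
    if window is not None:
        pts = tuple(p for p in pts if window[0] <= p[0] <= window[1])
    if len(pts) < 2:
        raise ValueError("need >= 2 points in the fit window")
    gamma_g_ml = np.array([p[0] for p in pts]) * 1e-3
    d = np.array([p[1] for p in pts])
    res = sm.OLS(d, sm.add_constant(gamma_g_ml)).fit()
    d0, slope = res.params          # D = d0 + slope*gamma; slope = d0*kD
    cov = res.cov_params()
    kd = slope / d0
    # delta method on f = slope/d0
    grad = np.array([-slope / d0**2, 1.0 / d0])
    kd_var = float(grad @ cov @ grad)
    win = (min(p[0] for p in pts), max(p[0] for p in pts))
    return KDFitResult(
        d0=float(d0),
        kd=float(kd),
        d0_se=float(res.bse[0]),
        kd_se=math.sqrt(max(kd_var, 0.0)),
        n_points=len(pts),
        window=win,
    )


def optical_constant(config: SLSConfig) -> float:
    """Debye optical constant K = 4 pi^2 n0^2 (dn/dc)^2 / (N_A lambda^4).

    With the wavelength in cm and dn/dc in mL/g, K carries cm^2 mol g^-2 so
    that K c / R is in mol/g for c in g/mL and R in cm^-1.
    """
    lam_cm = config.wavelength * 1e-7
    return (
        4 * math.pi**2 * config.refractive_index**2 * config.dn_dc**2
        / (AVOGADRO * lam_cm**4)
    )


def reduce_sls(series: SLSSeries) -> list[tuple[float, float]]:
    """Reduce a static-scattering series to (conc g/mL, Kc/R mol/g) points.

    Raw count rates are normalised by the laser intensity, referenced to the
    toluene standard (R_sample = I_sample/I_toluene * R_toluene) and combined
    with the optical constant. A series already holding Kc/R passes through.
    """
    if not series.raw:
        return [(c, v) for c, v in series.points]
    if series.toluene_count_rate is None or series.toluene_count_rate <= 0:
        raise ValueError("raw count-rate series needs a positive toluene count rate")
    if series.laser_intensity <= 0:
        raise ValueError("laser intensity must be > 0")
    k = optical_constant(series.config)
    i_tol = series.toluene_count_rate / series.laser_intensity
    out = []
    for c, mcr in series.points:
        i_sam = mcr / series.laser_intensity
        r_theta = i_sam / i_tol * series.config.rayleigh_toluene
        out.append((c, k * c / r_theta))
    return out


def debye_fit(
    points: Sequence[tuple[float, float]],
    window: tuple[float, float] | None = None,
) -> DebyeFitResult:
    """OLS Debye-plot fit: Kc/R = 1/Mw + 2*B22*c.

    A non-positive intercept (possible for strongly attractive systems) is
    reported with Mw = None and a warning; B22 is still returned.
    """
    pts = list(points)
    if window is not None:
        pts = [p for p in pts if window[0] <= p[0] <= window[1]]
    if len(pts) < 2:
        raise ValueError("need >= 2 points in the fit window")
    c = np.array([p[0] for p in pts])
    kcr = np.array([p[1] for p in pts])
    res = sm.OLS(kcr, sm.add_constant(c)).fit()
    intercept, slope = res.params
    b22 = slope / 2.0
    b22_se = float(res.bse[1]) / 2.0
    if intercept > 0:
        mw = 1.0 / intercept
        mw_se = float(res.bse[0]) / intercept**2
    else:
        warnings.warn("non-positive Debye intercept: Mw undefined", stacklevel=2)
        mw = mw_se = None
    win = (float(c.min()), float(c.max()))
    return DebyeFitResult(
        mw=mw,
        b22=float(b22),
        mw_se=mw_se,
        b22_se=b22_se,
        n_points=len(pts),
        window=win,
        intercept=float(intercept),
    )


def viscosity_from_flow(raw: ViscositySeries) -> list[tuple[float, float, float]]:
    """Ostwald reduction eta = eta0 (rho t)/(rho0 t0) -> (conc, eta, eta_rel)."""
    if raw.reference is None:
        raise ValueError("water reference (t0, rho0, eta0) required")
    t0, rho0, eta0 = raw.reference
    if t0 <= 0 or rho0 <= 0 or eta0 <= 0:
        raise ValueError("reference flow time, density and viscosity must be > 0")
    if not raw.raw:
        return [(c, rel * eta0, rel) for c, rel in raw.points]
    out = []
    for c, t, rho in raw.points:
        eta = eta0 * (rho * t) / (rho0 * t0)
        out.append((c, eta, eta / eta0))
    return out


def jones_dole_fit(
    points: Sequence[tuple[float, float]], fix_a: float | None = None
) -> JonesDoleFitResult:
    """Fit eta/eta0 - 1 = A sqrt(c) + B c by least squares in {sqrt(c), c}.

    ``fix_a`` pins the electrostatic A coefficient to a supplied
    (Debye-Hueckel) value and fits only B.
    """
    if len(points) < (1 if fix_a is not None else 2):
        raise ValueError("not enough points for the requested fit")
    c = np.array([p[0] for p in points], dtype=float)
    rel = np.array([p[1] for p in points], dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0 for the Jones-Dole basis")
    if len(np.unique(c)) < (1 if fix_a is not None else 2):
        raise ValueError("rank-deficient design")
    yv = rel - 1.0
    if fix_a is not None:
        yv = yv - fix_a * np.sqrt(c)
        res = sm.OLS(yv, c[:, None]).fit()
        return JonesDoleFitResult(
            a=float(fix_a),
            b=float(res.params[0]),
            a_se=0.0,
            b_se=float(res.bse[0]) if len(points) > 1 else 0.0,
            a_fixed=True,
        )
    design = np.column_stack([np.sqrt(c), c])
    res = sm.OLS(yv, design).fit()
    a_se, b_se = (float(s) for s in res.bse)
    if len(points) == 2:
        a_se = b_se = 0.0  # exact interpolation
    return JonesDoleFitResult(
        a=float(res.params[0]),
        b=float(res.params[1]),
        a_se=a_se,
        b_se=b_se,
        a_fixed=False,
    )


def concentration_from_absorbance(
    a280: float, path_cm: float = 1.0, extinction: float = 2.64
) -> float:
    """Beer-Lambert protein concentration, mg/mL, from absorbance at 280 nm.

    The default extinction coefficient 2.64 mL mg^-1 cm^-1 is the HEWL value.
    """
    if a280 < 0:
        raise ValueError("absorbance must be >= 0")
    if path_cm <= 0 or extinction <= 0:
        raise ValueError("path length and extinction must be > 0")
    return a280 / (extinction * path_cm)
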