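"""Spinodals, critical points, binodals and cloud points of the TPT1 model.

Because the well depth epsilon is temperature independent, every coexistence
condition depends on (T, epsilon) only through the reduced inverse
temperature y = epsilon/T. All solvers therefore work in the reduced
variables (eta, y): the critical point (y_c, eta_c) is a pure function of the
model geometry, and a cloud point obeys T_cloud(gamma; eps) = eps / y*(gamma)
with y*(gamma) cached per (model, gamma). Physical-unit wrappers convert at
the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, minimize_scalar, root

from .models import BufferInteraction, ProteinModel, density_from_packing, packing_fraction
from .thermo import (
    _mu_reduced,
    _pressure_reduced,
    _pressure_reduced_d1,
    _pressure_reduced_d2,
)

__all__ = [
    "CoexistencePoint",
    "BinodalCurve",
    "PhaseSolverError",
    "spinodal_densities",
    "critical_point",
    "coexistence_at_temperature",
    "binodal_curve",
    "cloud_point_temperature",
    "cloud_point_for_epsilon",
]

_ETA_LO = 1e-14      # smallest packing fraction the solvers consider
_ETA_HI = 0.68       # above this the liquid branch is unphysical here
_COEX_TOL = 1e-11    # residual tolerance on equal-P / equal-mu (reduced units)
_T_FLOOR_K = 150.0   # low-temperature cutoff for cloud-point searches


class PhaseSolverError(RuntimeError):
    """Raised when a phase-equilibrium solve fails; carries diagnostics."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class CoexistencePoint:
    """Dilute/dense coexistence densities at one temperature.

    ``residuals`` are the (delta beta*Pi, delta beta*mu) diagnostics in
    reduced units; both are below the solver tolerance by construction.
    """

    temperature: float
    rho_dilute: float
    rho_dense: float
    residuals: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.rho_dilute < self.rho_dense:
            raise ValueError("rho_dilute must be < rho_dense")


@dataclass(frozen=True)
class BinodalCurve:
    """Liquid-liquid coexistence curve with its critical point.

    ``points`` are sorted by increasing temperature; both branches merge at
    (critical_temperature, critical_density) at the top of the dome.
    """

    points: tuple[CoexistencePoint, ...]
    critical_temperature: float
    critical_density: float

    def gamma_branches(self, model: ProteinModel):
        """(T, gamma_dilute, gamma_dense) arrays in K and mg/mL."""
        t = np.array([p.temperature for p in self.points])
        lo = np.array([model.mass_concentration(p.rho_dilute) for p in self.points])
        hi = np.array([model.mass_concentration(p.rho_dense) for p in self.points])
        return t, lo, hi

    def to_dataframe(self, model: ProteinModel):
        import pandas as pd

        t, lo, hi = self.gamma_branches(model)
        return pd.DataFrame(
            {
                "T_K": t,
                "rho_dilute_nm3": [p.rho_dilute for p in self.points],
                "rho_dense_nm3": [p.rho_dense for p in self.points],
                "gamma_dilute_mg_ml": lo,
                "gamma_dense_mg_ml": hi,
            }
        )


# ---------------------------------------------------------------------------
# Reduced solvers (pure functions of model geometry and y = eps/T)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _critical_reduced(model: ProteinModel) -> tuple[float, float]:
    """(y_c, eta_c): the reduced critical point of a given geometry.

    Nested solve: eta*(y) minimises dP/deta (interior minimum, polished by
    Newton on d2P/deta2 = 0); y_c is the root of min_eta dP/deta = 0.
    """

    def eta_min(y: float) -> float:
        res = minimize_scalar(
            lambda e: _pressure_reduced_d1(e, y, model),
            bounds=(1e-4, 0.5),
            method="bounded",
            options={"xatol": 1e-12},
        )
        eta = res.x
        if not 2e-4 < eta < 0.499:
            return eta  # minimum at a bound: no interior inflection to polish
        for _ in range(8):  # Newton polish on d2P = 0
            f = _pressure_reduced_d2(eta, y, model)
            h = 1e-6
            fp = (
                _pressure_reduced_d2(eta + h, y, model)
                - _pressure_reduced_d2(eta - h, y, model)
            ) / (2 * h)
            step = f / fp
            if not math.isfinite(step) or abs(step) > 0.1:
                break
            eta = min(max(eta - step, 1e-5), 0.55)
            if abs(step) < 1e-15:
                break
        return eta

    def min_slope(y: float) -> float:
        return _pressure_reduced_d1(eta_min(y), y, model)

    ylo, yhi = 1.0, 2.0
    # expand until the minimum slope changes sign (supercritical -> subcritical)
    while min_slope(yhi) > 0:
        ylo, yhi = yhi, yhi * 1.6
        if yhi > 400:
            raise PhaseSolverError("no critical point found below y = eps/T = 400")
    if min_slope(ylo) < 0:
        ylo = ylo / 2
    y_c = brentq(min_slope, ylo, yhi, xtol=1e-13, rtol=8.9e-16)
    return y_c, eta_min(y_c)


def _spinodal_reduced(y: float, model: ProteinModel) -> tuple[float, float] | None:
    y_c, eta_c = _critical_reduced(model)
    if y <= y_c:
        return None
    lo = brentq(
        lambda e: _pressure_reduced_d1(e, y, model), _ETA_LO, eta_c,
        xtol=1e-16, rtol=8.9e-16,
    )
    hi = brentq(
        lambda e: _pressure_reduced_d1(e, y, model), eta_c, _ETA_HI,
        xtol=1e-16, rtol=8.9e-16,
    )
    return lo, hi


def _common_tangent_scan(y: float, model: ProteinModel, n_grid: int = 30000):
    """Grid-based common-tangent (lower convex hull) estimate of coexistence.

    Fallback initialiser: the hull edge of beta*A/V vs rho that spans the
    concave region connects the two coexisting densities.
    """
    from .thermo import _beta_a_reduced

    s = _spinodal_reduced(y, model)
    if s is None:
        raise PhaseSolverError(f"no two-phase region at y={y}")
    eta_lo = max(s[0] * 1e-4, 1e-12)
    eta_hi = min(s[1] * 1.35, _ETA_HI)
    grid = np.unique(
        np.concatenate(
            [
                np.geomspace(eta_lo, eta_hi, n_grid // 2),
                np.linspace(eta_lo, eta_hi, n_grid // 2),
            ]
        )
    )
    f = np.array([e * _beta_a_reduced(e, y, model) for e in grid])  # beta*A/V (eta units)
    # monotone-chain lower hull over (eta, f)
    hull: list[int] = []
    for i in range(len(grid)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (grid[i2] - grid[i1]) * (f[i] - f[i1]) - (grid[i] - grid[i1]) * (
                f[i2] - f[i1]
            )
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    gaps = np.diff(hull)
    k = int(np.argmax(gaps))
    return grid[hull[k]], grid[hull[k + 1]]


def _coexist_reduced(y: float, model: ProteinModel) -> tuple[float, float, tuple[float, float]]:
    """Solve equal-P, equal-mu in (ln eta_dilute, eta_dense) at reduced y."""
    s = _spinodal_reduced(y, model)
    if s is None:
        raise PhaseSolverError(f"y={y} is at or above the critical point")
    _, eta_c = _critical_reduced(model)
    s1, s2 = s

    def residual(x):
        e1, e2 = math.exp(x[0]), x[1]
        if not (0 < e1 < _ETA_HI and 0 < e2 < _ETA_HI):
            return [1e6, 1e6]
        return [
            _pressure_reduced(e1, y, model) - _pressure_reduced(e2, y, model),
            _mu_reduced(e1, y, model) - _mu_reduced(e2, y, model),
        ]

    def attempt(e1, e2):
        sol = root(residual, [math.log(e1), e2], method="hybr", tol=1e-14)
        r1, r2 = residual(sol.x)
        e1s, e2s = math.exp(sol.x[0]), sol.x[1]
        ok = (
            max(abs(r1), abs(r2)) < _COEX_TOL
            and e2s - e1s > 0.5 * (s2 - s1)  # reject the trivial equal root
            and e1s < s1 + 1e-12
            and e2s > s2 - 1e-12
        )
        return ok, e1s, e2s, (r1, r2)

    # mean-field near-critical seed: binodal half-width = sqrt(3) x spinodal's
    seeds = [
        (max(eta_c - math.sqrt(3.0) * (eta_c - s1), 0.3 * s1),
         min(eta_c + math.sqrt(3.0) * (s2 - eta_c), _ETA_HI)),
        (0.3 * s1, min(1.5 * s2, _ETA_HI)),
    ]
    for e1, e2 in seeds:
        ok, e1s, e2s, res = attempt(e1, e2)
        if ok:
            return e1s, e2s, res
    # fall back to the common-tangent grid scan, then polish
    e1, e2 = _common_tangent_scan(y, model)
    ok, e1s, e2s, res = attempt(e1, e2)
    if ok:
        return e1s, e2s, res
    raise PhaseSolverError(
        f"coexistence solve failed at y={y}", last_iterate=(e1s, e2s, res)
    )


@lru_cache(maxsize=None)
def _branch_y_reduced(model: ProteinModel, eta_target: float) -> float:
    """y at which eta_target lies on the binodal (dilute or dense branch)."""
    y_c, eta_c = _critical_reduced(model)
    if eta_target <= 0:
        raise ValueError("target packing fraction must be > 0")
    if abs(eta_target - eta_c) < 1e-12:
        return y_c
    dilute = eta_target < eta_c
    idx = 0 if dilute else 1

    def offset(y: float) -> float:
        e = _coexist_reduced(y, model)[idx]
        return (e - eta_target) if dilute else (eta_target - e)

    # expand the bracket away from y_c until the branch passes the target
    dy = y_c * 1e-4
    ylo = y_c + dy
    while offset(ylo) < 0:
        dy /= 4
        ylo = y_c + dy
        if dy < 1e-12 * y_c:
            # target essentially at the critical density
            return y_c
    yhi = y_c + y_c * 1e-3
    while offset(yhi) > 0:
        yhi = y_c + (yhi - y_c) * 2.0
        if yhi > 200:
            raise PhaseSolverError(
                f"eta={eta_target} is outside the coexistence dome for all y <= 200"
            )
    return brentq(offset, ylo, yhi, xtol=1e-13, rtol=8.9e-16)


# ---------------------------------------------------------------------------
# Public physical-unit API
# ---------------------------------------------------------------------------

def spinodal_densities(
    temperature: float, model: ProteinModel, eps: float
) -> tuple[float, float] | None:
    """Roots of d(beta*Pi)/d(rho) = 0 at T, in nm^-3; None above T_c."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    s = _spinodal_reduced(eps / temperature, model)
    if s is None:
        return None
    return (
        density_from_packing(s[0], model.sigma),
        density_from_packing(s[1], model.sigma),
    )


def critical_point(model: ProteinModel, eps: float) -> tuple[float, float]:
    """Critical temperature (K) and density (nm^-3) for the given well depth."""
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    y_c, eta_c = _critical_reduced(model)
    return eps / y_c, density_from_packing(eta_c, model.sigma)


def coexistence_at_temperature(
    temperature: float, model: ProteinModel, eps: float
) -> CoexistencePoint:
    """Dilute/dense coexistence densities at T with equal beta*Pi and beta*mu."""
    t_c, _ = critical_point(model, eps)
    if not 0 < temperature < t_c:
        raise ValueError(
            f"temperature {temperature} K not below the critical point {t_c:.3f} K"
        )
    e1, e2, res = _coexist_reduced(eps / temperature, model)
    return CoexistencePoint(
        temperature=temperature,
        rho_dilute=density_from_packing(e1, model.sigma),
        rho_dense=density_from_packing(e2, model.sigma),
        residuals=res,
    )


def binodal_curve(
    model: ProteinModel,
    eps: float,
    n_temperatures: int = 40,
    t_min_fraction: float = 0.8,
) -> BinodalCurve:
    """Liquid-liquid coexistence curve by downward continuation in T.

    Temperatures start at T_c (1 - 1e-3) and step geometrically down to
    ``t_min_fraction * T_c``; output points are sorted by increasing T.
    """
    if not 0 < t_min_fraction < 1:
        raise ValueError("t_min_fraction must be in (0, 1)")
    if n_temperatures < 2:
        raise ValueError("n_temperatures must be >= 2")
    t_c, rho_c = critical_point(model, eps)
    d0, d1 = 1e-3, 1.0 - t_min_fraction
    ratio = (d1 / d0) ** (1.0 / (n_temperatures - 1))
    deltas = d0 * ratio ** np.arange(n_temperatures)
    points = []
    for d in deltas:
        points.append(coexistence_at_temperature(t_c * (1.0 - d), model, eps))
    points.sort(key=lambda p: p.temperature)
    return BinodalCurve(
        points=tuple(points), critical_temperature=t_c, critical_density=rho_c
    )


def cloud_point_for_epsilon(gamma: float, model: ProteinModel, eps: float) -> float:
    """Cloud-point temperature (K) at mass concentration gamma for depth eps.

    The temperature at which gamma crosses the binodal (dilute branch for
    gamma below the critical concentration, dense branch above; exactly the
    critical temperature at the critical concentration). Uses the reduced
    identity T_cloud = eps / y*(gamma); the scalar root for y* is solved to
    far better than 1e-3 K and cached per (model, gamma).
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    eta = packing_fraction(model.number_density(gamma), model.sigma)
    y_star = _branch_y_reduced(model, eta)
    t = eps / y_star
    if t < _T_FLOOR_K:
        raise PhaseSolverError(
            f"cloud point {t:.1f} K below the {_T_FLOOR_K} K search floor"
        )
    return t


def cloud_point_temperature(
    gamma: float,
    model: ProteinModel,
    buffer: BufferInteraction,
    ionic_strength: float = 0.0,
) -> float:
    """Cloud-point temperature (K) in a buffer at a given ionic strength.

    The effective depth is epsilon(I) = eps0 + a*sqrt(I); the cloud point is
    the binodal crossing of gamma at that depth.
    """
    return cloud_point_for_epsilon(gamma, model, buffer.epsilon(ionic_strength))
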