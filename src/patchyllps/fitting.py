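"""Calibration of buffer interaction parameters from cloud-point data.

Pipeline: each measured cloud point (I, T_cloud) is inverted to the well
depth epsilon that reproduces it; the per-salt depths are then regressed
against sqrt(I) to give the zero-salt depth eps0 (intercept) and the salt
coefficient a (slope). Raw cloud points measured at several salt
concentrations can be extrapolated to zero salt, and simple linear
correlation analyses connect the fitted parameters to the measured
interaction indicators (kD, B22, Jones-Dole B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .models import BufferInteraction, ProteinModel
from .phase import PhaseSolverError, cloud_point_for_epsilon

__all__ = [
    "CloudPointSeries",
    "LinearFitResult",
    "EpsilonPoint",
    "SaltFitResult",
    "ZeroSaltExtrapolation",
    "fit_eps0",
    "fit_epsilon_series",
    "fit_salt_coefficients",
    "extrapolate_tcloud_zero_salt",
    "linear_correlation",
]

_EPS_BRACKET = (500.0, 5000.0)


@dataclass(frozen=True)
class CloudPointSeries:
    """Cloud-point temperatures vs ionic strength at one protein concentration.

    ``observations`` is a sequence of (ionic_strength M, t_cloud K,
    sigma_t K or None) triples with strictly increasing non-negative ionic
    strengths.
    """

    buffer_name: str
    gamma: float
    observations: tuple[tuple[float, float, float | None], ...]
    meta: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        obs = tuple(
            (float(i), float(t), None if s is None else float(s))
            for i, t, s in self.observations
        )
        object.__setattr__(self, "observations", obs)
        iv = [o[0] for o in obs]
        if any(i < 0 for i in iv):
            raise ValueError("ionic strengths must be non-negative")
        if any(b <= a for a, b in zip(iv, iv[1:])):
            raise ValueError("ionic strengths must be strictly increasing")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    @property
    def ionic_strengths(self) -> np.ndarray:
        return np.array([o[0] for o in self.observations])

    @property
    def t_cloud(self) -> np.ndarray:
        return np.array([o[1] for o in self.observations])

    @property
    def sigma_t(self) -> np.ndarray:
        return np.array(
            [math.nan if o[2] is None else o[2] for o in self.observations]
        )


@dataclass(frozen=True)
class LinearFitResult:
    """Ordinary least-squares line with standard errors and Pearson r."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    pearson_r: float


@dataclass(frozen=True)
class EpsilonPoint:
    """Well depth inverted from one cloud-point observation."""

    ionic_strength: float
    eps: float            # K; nan when the inversion failed
    eps_se: float | None  # propagated from sigma_t when available
    message: str | None = None

    @property
    def ok(self) -> bool:
        return math.isfinite(self.eps)


@dataclass(frozen=True)
class SaltFitResult:
    """eps0/a regression result packaged as a BufferInteraction + uncertainties."""

    buffer: BufferInteraction
    eps0_se: float
    salt_coeff_se: float
    n_points: int
    weighted: bool


@dataclass(frozen=True)
class ZeroSaltExtrapolation:
    """Zero-salt intercept of a cloud-point vs salt-concentration series."""

    t_cloud_0: float
    se: float
    basis: str  # "linear" (in c) or "sqrt" (in sqrt c)


def fit_eps0(
    model: ProteinModel,
    gamma: float,
    t_cloud_obs: float,
    bracket: tuple[float, float] = _EPS_BRACKET,
) -> float:
    """Well depth (K) whose cloud point at ``gamma`` equals ``t_cloud_obs``.

    T_cloud is strictly increasing (in fact proportional) in epsilon at fixed
    geometry and concentration, so the inversion is unique:
    eps = t_cloud_obs * y*(gamma), with y*(gamma) the reduced cloud-point
    temperature solved once and cached. Raises a bracket error when the
    required depth falls outside ``bracket``.
    """
    if t_cloud_obs <= 0:
        raise ValueError("t_cloud_obs must be > 0 K")
    # y*(gamma) = eps / T_cloud for any eps; evaluate at the bracket midpoint
    eps_ref = 0.5 * (bracket[0] + bracket[1])
    y_star = eps_ref / cloud_point_for_epsilon(gamma, model, eps_ref)
    eps = t_cloud_obs * y_star
    if not bracket[0] <= eps <= bracket[1]:
        raise PhaseSolverError(
            f"target T_cloud={t_cloud_obs} K needs eps={eps:.1f} K, outside "
            f"bracket {bracket}; reachable T_cloud range is "
            f"[{bracket[0] / y_star:.2f}, {bracket[1] / y_star:.2f}] K",
            last_iterate=eps,
        )
    return eps


def fit_epsilon_series(
    series: CloudPointSeries, model: ProteinModel
) -> list[EpsilonPoint]:
    """Invert every observation of a series to a well depth epsilon(I).

    Per-point failures (cloud point outside the reachable bracket) are
    reported in the returned records, not raised.
    """
    out: list[EpsilonPoint] = []
    for ionic, t_obs, sig in series.observations:
        try:
            eps = fit_eps0(model, series.gamma, t_obs)
        except (PhaseSolverError, ValueError) as exc:
            out.append(EpsilonPoint(ionic, math.nan, None, message=str(exc)))
            continue
        se = None
        if sig is not None:
            # d eps / d T_cloud = eps / T_cloud (proportionality)
            se = sig * eps / t_obs
        out.append(EpsilonPoint(ionic, eps, se))
    return out


def fit_salt_coefficients(
    eps_points: Sequence[EpsilonPoint | tuple[float, float]],
    name: str = "fitted",
) -> SaltFitResult:
    """Regress epsilon against sqrt(I): intercept eps0, slope a.

    Inverse-variance weighting is used when every point carries a standard
    error; otherwise the fit is unweighted. Requires at least two distinct
    ionic strengths.
    """
    pts: list[tuple[float, float, float | None]] = []
    for p in eps_points:
        if isinstance(p, EpsilonPoint):
            if p.ok:
                pts.append((p.ionic_strength, p.eps, p.eps_se))
        else:
            ionic, eps = p
            pts.append((float(ionic), float(eps), None))
    if len(pts) < 2:
        raise ValueError("need >= 2 successfully inverted points")
    x = np.sqrt([p[0] for p in pts])
    yv = np.array([p[1] for p in pts])
    if len(np.unique(x)) < 2:
        raise ValueError("rank-deficient design: need >= 2 distinct ionic strengths")
    design = sm.add_constant(x)
    ses = [p[2] for p in pts]
    weighted = all(s is not None and s > 0 for s in ses)
    with np.errstate(divide="ignore", invalid="ignore"):  # 2-point fits: df_resid=0
        if weighted:
            res = sm.WLS(yv, design, weights=1.0 / np.asarray(ses, dtype=float) ** 2).fit()
        else:
            res = sm.OLS(yv, design).fit()
        eps0, slope = res.params
        eps0_se, slope_se = res.bse
    if len(pts) == 2:
        eps0_se = slope_se = 0.0  # exact interpolation
    buffer = BufferInteraction(name=name, eps0=float(eps0), salt_coeff=float(slope))
    return SaltFitResult(
        buffer=buffer,
        eps0_se=float(eps0_se),
        salt_coeff_se=float(slope_se),
        n_points=len(pts),
        weighted=weighted,
    )


def extrapolate_tcloud_zero_salt(
    raw: Sequence[tuple[float, float]], basis: str = "linear"
) -> ZeroSaltExtrapolation:
    """Least-squares zero-salt intercept of cloud points vs salt concentration.

    ``basis`` selects the regression abscissa: ``"linear"`` fits T against c,
    ``"sqrt"`` against sqrt(c); the choice is recorded in the result.
    """
    if len(raw) < 2:
        raise ValueError("need >= 2 points to extrapolate")
    c = np.array([p[0] for p in raw], dtype=float)
    t = np.array([p[1] for p in raw], dtype=float)
    if basis == "linear":
        x = c
    elif basis == "sqrt":
        x = np.sqrt(c)
    else:
        raise ValueError(f"unknown basis {basis!r}; use 'linear' or 'sqrt'")
    res = sm.OLS(t, sm.add_constant(x)).fit()
    se = float(res.bse[0]) if len(raw) > 2 else 0.0
    return ZeroSaltExtrapolation(t_cloud_0=float(res.params[0]), se=se, basis=basis)


def linear_correlation(xs: Sequence[float], ys: Sequence[float]) -> LinearFitResult:
    """OLS slope/intercept with standard errors and the Pearson correlation."""
    x = np.asarray(xs, dtype=float)
    yv = np.asarray(ys, dtype=float)
    if x.shape != yv.shape or x.size < 2:
        raise ValueError("xs and ys must have equal length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sm.OLS(yv, sm.add_constant(x)).fit()
    if np.ptp(yv) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(x, yv).statistic)
    return LinearFitResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        pearson_r=r,
    )
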