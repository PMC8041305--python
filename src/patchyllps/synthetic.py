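"""Seeded synthetic measurement streams with known ground truth.

Every input the calibration and reduction stages consume can be generated
here from stated true parameters: cloud-point series come from the TPT1
binodal itself with epsilon(I) = eps0 + a*sqrt(I); diffusion, Debye and
Jones-Dole series come from their exact model curves. Noise is additive
Gaussian on the measured ordinate (the simplest model consistent with
symmetric reported uncertainties), and identical (spec, seed) inputs give
byte-identical output. The generated series do not emulate instrument
systematics (drift, stray light, polydispersity); what a passing fit
demonstrates is correctness of the estimators, not robustness to such
artefacts.

Default grids mirror typical bench practice for lysozyme work: NaBr ionic
strengths 0.1-0.5 M, DLS concentrations 4-70 mg/mL, viscometry 0.02-0.1 M.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .fitting import CloudPointSeries
from .models import BufferInteraction, ProteinModel
from .phase import cloud_point_temperature
from .reduction import DLSSeries, SLSConfig, SLSSeries, ViscositySeries, optical_constant

__all__ = [
    "GeneratorSpec",
    "DEFAULT_IONIC_STRENGTHS",
    "DEFAULT_DLS_GAMMAS",
    "DEFAULT_VISC_CONCS",
    "gen_cloud_point_series",
    "gen_dls_series",
    "gen_sls_series",
    "gen_viscosity_series",
    "generate",
    "hewl_model",
    "buffer_fixtures",
]

DEFAULT_IONIC_STRENGTHS = (0.1, 0.2, 0.3, 0.4, 0.5)  # M NaBr
DEFAULT_DLS_GAMMAS = tuple(np.linspace(4.0, 70.0, 8))  # mg/mL
DEFAULT_SLS_CONCS = tuple(np.linspace(1.0, 9.0, 8) * 1e-3)  # g/mL
DEFAULT_VISC_CONCS = (0.02, 0.04, 0.06, 0.08, 0.10)  # mol/L


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic stream.

    ``kind`` is one of {"cloudpoint", "dls", "sls", "viscosity"}; ``truth``
    holds the generating parameters for that kind; ``grid`` the abscissa
    values; ``noise_sd`` the Gaussian noise level in the ordinate's units.
    """

    kind: str
    truth: dict = field(hash=False)
    grid: tuple[float, ...]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in {"cloudpoint", "dls", "sls", "viscosity"}:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        grid = tuple(float(g) for g in self.grid)
        if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be non-empty and strictly increasing")
        object.__setattr__(self, "grid", grid)


def gen_cloud_point_series(
    model: ProteinModel,
    buffer: BufferInteraction,
    gamma: float,
    ionic_strengths: Sequence[float] = DEFAULT_IONIC_STRENGTHS,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> CloudPointSeries:
    """Cloud points T_cloud(I) from the model binodal, plus Gaussian noise.

    The truth (eps0, a, gamma, noise_sd, seed) is recorded in ``meta``.
    Raises naming the offending ionic strength when the requested state is
    outside the reachable coexistence dome.
    """
    rng = np.random.default_rng(seed)
    obs = []
    for ionic in ionic_strengths:
        try:
            t = cloud_point_temperature(gamma, model, buffer, ionic)
        except Exception as exc:
            raise ValueError(
                f"ionic strength {ionic} M: cloud point unreachable ({exc})"
            ) from exc
        t_noisy = t + rng.normal(0.0, noise_sd) if noise_sd > 0 else t
        obs.append((float(ionic), float(t_noisy), noise_sd if noise_sd > 0 else None))
    return CloudPointSeries(
        buffer_name=buffer.name,
        gamma=gamma,
        observations=tuple(obs),
        meta={
            "truth": {"eps0": buffer.eps0, "salt_coeff": buffer.salt_coeff},
            "gamma": gamma,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def gen_dls_series(
    d0: float,
    kd: float,
    gammas: Sequence[float] = DEFAULT_DLS_GAMMAS,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature: float = 298.15,
    solvent_viscosity: float = 0.8900,
) -> DLSSeries:
    """D(gamma) = d0*(1 + kd*gamma) with gamma in mg/mL, kd in mL/g; + noise."""
    rng = np.random.default_rng(seed)
    pts = []
    for g in gammas:
        d = d0 * (1.0 + kd * g * 1e-3)
        if noise_sd > 0:
            d += rng.normal(0.0, noise_sd)
        pts.append((float(g), float(d)))
    return DLSSeries(
        points=tuple(pts),
        solvent_viscosity=solvent_viscosity,
        temperature=temperature,
        meta={"truth": {"d0": d0, "kd": kd}, "noise_sd": noise_sd, "seed": seed},
    )


def gen_sls_series(
    mw: float,
    b22: float,
    concs: Sequence[float] = DEFAULT_SLS_CONCS,
    config: SLSConfig = SLSConfig(),
    noise_sd: float = 0.0,
    seed: int = 0,
    as_count_rates: bool = False,
    laser_intensity: float = 1.0,
    toluene_count_rate: float = 1.0e5,
) -> SLSSeries:
    """Debye-line series Kc/R = 1/mw + 2*b22*c, optionally as raw count rates.

    Noise is additive Gaussian on Kc/R (mol/g); when ``as_count_rates`` the
    noisy Kc/R is converted back to mean count rates through the toluene
    reference, so the round trip through :func:`reduce_sls` is exact.
    """
    rng = np.random.default_rng(seed)
    k = optical_constant(config)
    pts = []
    for c in concs:
        kcr = 1.0 / mw + 2.0 * b22 * c
        if noise_sd > 0:
            kcr += rng.normal(0.0, noise_sd)
        if as_count_rates:
            r_theta = k * c / kcr
            i_tol = toluene_count_rate / laser_intensity
            mcr = r_theta / config.rayleigh_toluene * i_tol * laser_intensity
            pts.append((float(c), float(mcr)))
        else:
            pts.append((float(c), float(kcr)))
    return SLSSeries(
        points=tuple(pts),
        raw=as_count_rates,
        laser_intensity=laser_intensity,
        toluene_count_rate=toluene_count_rate if as_count_rates else None,
        config=config,
        meta={"truth": {"mw": mw, "b22": b22}, "noise_sd": noise_sd, "seed": seed},
    )


def gen_viscosity_series(
    a: float,
    b: float,
    concs: Sequence[float] = DEFAULT_VISC_CONCS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ViscositySeries:
    """Jones-Dole curve eta_rel = 1 + a*sqrt(c) + b*c, plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    pts = []
    for c in concs:
        rel = 1.0 + a * np.sqrt(c) + b * c
        if noise_sd > 0:
            rel += rng.normal(0.0, noise_sd)
        pts.append((float(c), float(rel)))
    return ViscositySeries(
        points=tuple(pts),
        raw=False,
        meta={"truth": {"a": a, "b": b}, "noise_sd": noise_sd, "seed": seed},
    )


def generate(spec: GeneratorSpec, model: ProteinModel | None = None):
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    if spec.kind == "cloudpoint":
        if model is None:
            model = hewl_model()
        buffer = BufferInteraction(
            name=spec.truth.get("name", "synthetic"),
            eps0=spec.truth["eps0"],
            salt_coeff=spec.truth["salt_coeff"],
        )
        return gen_cloud_point_series(
            model, buffer, spec.truth["gamma"], spec.grid, spec.noise_sd, spec.seed
        )
    if spec.kind == "dls":
        return gen_dls_series(
            spec.truth["d0"], spec.truth["kd"], spec.grid, spec.noise_sd, spec.seed
        )
    if spec.kind == "sls":
        return gen_sls_series(
            spec.truth["mw"], spec.truth["b22"], spec.grid,
            noise_sd=spec.noise_sd, seed=spec.seed,
        )
    return gen_viscosity_series(
        spec.truth["a"], spec.truth["b"], spec.grid, spec.noise_sd, spec.seed
    )


def _load_fixture_payload() -> dict:
    with resources.files("patchyllps.data").joinpath("hewl_parameters.json").open() as fh:
        return json.load(fh)


def hewl_model() -> ProteinModel:
    """Packaged HEWL coarse-grained model (sigma, omega, M, M2)."""
    return ProteinModel.from_dict(_load_fixture_payload()["model"])


def buffer_fixtures() -> list[BufferInteraction]:
    """Packaged per-buffer parameter sets (phosphate, HEPES, MOPS, cacodylate).

    Each carries the fitted (eps0, a) with reported uncertainties, plus the
    measured kD, B22 and Jones-Dole B values as metadata.
    """
    payload = _load_fixture_payload()
    return [BufferInteraction.from_dict(b) for b in payload["buffers"]]
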