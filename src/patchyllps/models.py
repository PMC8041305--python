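"""Coarse-grained protein and buffer parameter objects.

The protein is a hard sphere of diameter ``sigma`` decorated with ``n_sites``
equivalent short-range square-well bonding sites placed at distance
``sigma/2`` from the centre (on the surface). A buffer is characterised by
the square-well depth at zero added salt, ``eps0`` (in kelvin, i.e.
epsilon/k_B), and a salt coefficient ``salt_coeff`` scaling the sqrt(ionic
strength) response of the effective protein-protein attraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

from .constants import AVOGADRO, NM3_PER_LITER

__all__ = [
    "ProteinModel",
    "BufferInteraction",
    "StatePoint",
    "number_density",
    "mass_concentration",
    "packing_fraction",
    "density_from_packing",
]

_SCHEMA_TAG = "patchyllps/parameters-v1"


def number_density(gamma: float, molar_mass: float) -> float:
    """Convert a mass concentration to a number density.

    Parameters
    ----------
    gamma : float
        Mass concentration in mg/mL (equivalently g/L).
    molar_mass : float
        Molar mass in g/mol.

    Returns
    -------
    float
        Number density in nm^-3.
    """
    if gamma < 0:
        raise ValueError(f"mass concentration must be >= 0, got {gamma}")
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be > 0, got {molar_mass}")
    # mg/mL == g/L; g/L / (g/mol) = mol/L; mol/L * N_A / (nm^3 per L) = nm^-3
    return gamma / molar_mass * AVOGADRO / NM3_PER_LITER


def mass_concentration(rho: float, molar_mass: float) -> float:
    """Inverse of :func:`number_density`: nm^-3 -> mg/mL."""
    if rho < 0:
        raise ValueError(f"number density must be >= 0, got {rho}")
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be > 0, got {molar_mass}")
    return rho * NM3_PER_LITER / AVOGADRO * molar_mass


_ETA_MAX = 0.74  # close packing; the theory is meaningless beyond it


def packing_fraction(rho: float, sigma: float) -> float:
    """Hard-sphere packing fraction eta = pi*rho*sigma^3/6.

    Raises
    ------
    ValueError
        If ``rho`` is negative or eta would reach close packing (0.74).
    """
    if rho < 0:
        raise ValueError(f"number density must be >= 0, got {rho}")
    eta = math.pi * rho * sigma**3 / 6.0
    if eta >= _ETA_MAX:
        raise ValueError(f"packing fraction {eta:.4f} beyond close packing")
    return eta


def density_from_packing(eta: float, sigma: float) -> float:
    """Inverse of :func:`packing_fraction`: eta -> nm^-3."""
    if not 0 <= eta < _ETA_MAX:
        raise ValueError(f"packing fraction out of range: {eta}")
    return 6.0 * eta / (math.pi * sigma**3)


@dataclass(frozen=True)
class ProteinModel:
    """Geometry and valence of the coarse-grained protein.

    Attributes
    ----------
    sigma : float
        Hard-sphere diameter in nm.
    omega : float
        Square-well range of the site-site attraction in nm.
    n_sites : int
        Number M of equivalent attractive surface sites.
    molar_mass : float
        Protein molar mass M2 in g/mol.
    """

    sigma: float
    omega: float
    n_sites: int
    molar_mass: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0 < self.omega < self.sigma:
            raise ValueError(f"omega must be in (0, sigma), got {self.omega}")
        if int(self.n_sites) != self.n_sites or self.n_sites < 1:
            raise ValueError(f"n_sites must be a positive integer, got {self.n_sites}")
        object.__setattr__(self, "n_sites", int(self.n_sites))
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")

    @property
    def site_distance(self) -> float:
        """Distance d of each site from the sphere centre; always sigma/2."""
        return self.sigma / 2.0

    def number_density(self, gamma: float) -> float:
        """Mass concentration mg/mL -> number density nm^-3 for this protein."""
        return number_density(gamma, self.molar_mass)

    def mass_concentration(self, rho: float) -> float:
        """Number density nm^-3 -> mass concentration mg/mL for this protein."""
        return mass_concentration(rho, self.molar_mass)

    def packing_fraction_of_gamma(self, gamma: float) -> float:
        return packing_fraction(self.number_density(gamma), self.sigma)

    def to_dict(self) -> dict[str, Any]:
        return {"schema": _SCHEMA_TAG, **asdict(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ProteinModel":
        return cls(
            sigma=float(d["sigma"]),
            omega=float(d["omega"]),
            n_sites=int(d["n_sites"]),
            molar_mass=float(d["molar_mass"]),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ProteinModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class BufferInteraction:
    """Per-buffer energetics of the effective protein-protein attraction.

    Attributes
    ----------
    name : str
        Buffer label (e.g. ``"phosphate"``).
    eps0 : float
        Square-well depth at zero added simple salt, as epsilon0/k_B in K.
    salt_coeff : float
        Salt response coefficient ``a`` in K L^(1/2) mol^(-1/2).
    jones_dole_b : float or None
        Jones-Dole viscosity B coefficient of the buffer, L/mol (metadata).
    metadata : mapping or None
        Free-form extra metadata (uncertainties, measured kD/B22, ...).
    """

    name: str
    eps0: float
    salt_coeff: float
    jones_dole_b: float | None = None
    metadata: Mapping[str, Any] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.eps0 <= 0:
            raise ValueError(f"eps0 must be > 0, got {self.eps0}")
        if not math.isfinite(self.salt_coeff):
            raise ValueError("salt_coeff must be finite")

    def epsilon(self, ionic_strength: float) -> float:
        """Effective well depth epsilon(I) = eps0 + a*sqrt(I), in K."""
        if ionic_strength < 0:
            raise ValueError(f"ionic strength must be >= 0, got {ionic_strength}")
        return self.eps0 + self.salt_coeff * math.sqrt(ionic_strength)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "schema": _SCHEMA_TAG,
            "name": self.name,
            "eps0": self.eps0,
            "salt_coeff": self.salt_coeff,
        }
        if self.jones_dole_b is not None:
            d["jones_dole_b"] = self.jones_dole_b
        if self.metadata is not None:
            d["metadata"] = dict(self.metadata)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "BufferInteraction":
        return cls(
            name=str(d["name"]),
            eps0=float(d["eps0"]),
            salt_coeff=float(d["salt_coeff"]),
            jones_dole_b=(float(d["jones_dole_b"]) if d.get("jones_dole_b") is not None else None),
            metadata=d.get("metadata"),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BufferInteraction":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class StatePoint:
    """One thermodynamic state: temperature, composition, ionic strength.

    ``gamma`` (mg/mL) and ``rho`` (nm^-3) are kept mutually consistent via the
    protein molar mass used at construction.
    """

    temperature: float
    gamma: float
    rho: float
    ionic_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.gamma < 0 or self.rho < 0:
            raise ValueError("concentration must be >= 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @classmethod
    def from_concentration(
        cls,
        temperature: float,
        gamma: float,
        model: ProteinModel,
        ionic_strength: float = 0.0,
    ) -> "StatePoint":
        return cls(temperature, gamma, model.number_density(gamma), ionic_strength)

    @classmethod
    def from_density(
        cls,
        temperature: float,
        rho: float,
        model: ProteinModel,
        ionic_strength: float = 0.0,
    ) -> "StatePoint":
        return cls(temperature, model.mass_concentration(rho), rho, ionic_strength)
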