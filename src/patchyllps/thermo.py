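"""Wertheim first-order thermodynamic perturbation theory (TPT1) state functions.

The protein fluid is a one-component system of hard spheres (diameter sigma)
carrying M equivalent square-well surface sites of depth epsilon and range
omega at distance d = sigma/2 from the centre. The Helmholtz free energy is
additive,

    beta*A/N = beta*A_id/N + beta*A_hs/N + beta*A_ass/N,

with the Carnahan-Starling hard-sphere term and the TPT1 association term

    beta*A_ass/N = M (ln X - X/2 + 1/2),

where the monomer (unbonded-site) fraction X solves the mass-action law
X + M*rho*Delta*X^2 = 1. The association strength Delta is evaluated in the
sticky limit as the Percus-Yevick contact value of g_hs times the radial
integral of the orientation-averaged Mayer function of one site pair,

    Delta = 4*pi*g_hs(sigma) * Int_sigma^{sigma+omega} fbar(r) r^2 dr,
    fbar(r) = (e^{beta*eps} - 1) (sigma+omega-r)^2 (2*omega+r-sigma) / (6*sigma^2*r).

Osmotic pressure and chemical potential follow by analytic differentiation;
because epsilon is temperature independent, every dimensionless state
function depends on (T, epsilon) only through y = epsilon/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, ML_PER_NM3, THERMAL_WAVELENGTH_NM
from .models import BufferInteraction, ProteinModel, packing_fraction

__all__ = [
    "ThermoEvaluation",
    "SecondVirial",
    "ghs_contact",
    "pair_boltzmann_config_energy",
    "mayer_angular_average",
    "association_strength",
    "monomer_fraction",
    "free_energy",
    "osmotic_pressure",
    "chemical_potential",
    "evaluate_state",
    "second_virial",
    "epsilon_at_ionic_strength",
]


@dataclass(frozen=True)
class ThermoEvaluation:
    """All single-state TPT1 quantities at one (rho, T, epsilon).

    Free-energy parts are beta*A/N (dimensionless per particle); pressure is
    beta*Pi in nm^-3; chemical potential beta*mu is dimensionless.
    """

    monomer_fraction: float
    beta_a_ideal: float
    beta_a_hs: float
    beta_a_assoc: float
    beta_pressure: float | None = None
    beta_mu: float | None = None

    @property
    def beta_a_total(self) -> float:
        return self.beta_a_ideal + self.beta_a_hs + self.beta_a_assoc


@dataclass(frozen=True)
class SecondVirial:
    """Second virial coefficient in model units and in the scattering unit."""

    b2_nm3: float
    b22_mol_ml_g2: float


def ghs_contact(eta: float) -> float:
    """Percus-Yevick hard-sphere contact value g_hs(sigma) = (1+eta/2)/(1-eta)^2."""
    if not 0 <= eta < 1:
        raise ValueError(f"packing fraction out of [0,1): {eta}")
    return (1 + eta / 2.0) / (1 - eta) ** 2


def _ghs_prime(eta: float) -> float:
    return (5 + eta) / (2 * (1 - eta) ** 3)


def _ghs_second(eta: float) -> float:
    return (8 + eta) / (1 - eta) ** 4


# ---------------------------------------------------------------------------
# Pair potential and orientation-averaged Mayer function
# ---------------------------------------------------------------------------

def pair_boltzmann_config_energy(
    r: float,
    orientations_1: np.ndarray,
    orientations_2: np.ndarray,
    model: ProteinModel,
    eps: float,
) -> float:
    """Configurational pair energy u/k_B (K) for explicit site orientations.

    ``orientations_1`` and ``orientations_2`` are (k, 3) arrays of unit
    vectors giving site directions on each sphere; sites sit at distance
    d = sigma/2 from each centre and the centres are separated by ``r`` along
    the z axis. A site pair contributes -eps when the site-site distance is
    within omega; each site may bond at most once (single-bond rule), extra
    geometric contacts are discarded greedily. Hard overlap (r < sigma)
    returns +inf.

    This is the brute-force route used by the Monte-Carlo oracle for the
    orientation-averaged Mayer function; the analytic theory never calls it.
    """
    if r <= 0:
        raise ValueError(f"separation must be > 0, got {r}")
    if r < model.sigma:
        return math.inf
    o1 = np.atleast_2d(np.asarray(orientations_1, dtype=float))
    o2 = np.atleast_2d(np.asarray(orientations_2, dtype=float))
    d = model.site_distance
    s1 = d * o1                                  # sites on sphere 1
    s2 = d * o2 + np.array([0.0, 0.0, r])        # sites on sphere 2
    dist = np.linalg.norm(s1[:, None, :] - s2[None, :, :], axis=-1)
    in_range = dist <= model.omega
    # single-bond rule: one partner per site, closest pairs first
    bonds = 0
    used1: set[int] = set()
    used2: set[int] = set()
    for i, j in sorted(zip(*np.nonzero(in_range)), key=lambda ij: dist[ij]):
        if i not in used1 and j not in used2:
            used1.add(i)
            used2.add(j)
            bonds += 1
    return -eps * bonds


def mayer_angular_average(
    r: float, temperature: float, eps: float, model: ProteinModel
) -> float:
    """Orientation-averaged Mayer function fbar(r) of one site pair.

    Closed form for surface sites (d = sigma/2):

        fbar(r) = (e^{eps/T} - 1) (sigma+omega-r)^2 (2*omega + r - sigma)
                  / (6 sigma^2 r),   sigma <= r <= sigma + omega,

    and 0 beyond the geometric cutoff sigma + omega.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    if r < model.sigma:
        raise ValueError(f"r={r} below contact sigma={model.sigma}")
    sigma, omega = model.sigma, model.omega
    if r >= sigma + omega:
        return 0.0
    boltz = math.expm1(eps / temperature)
    return boltz * (sigma + omega - r) ** 2 * (2 * omega + r - sigma) / (6 * sigma**2 * r)


def _bond_volume(model: ProteinModel, y: float) -> float:
    """4*pi * Int fbar(r) r^2 dr in nm^3, with y = eps/T.

    The radial integral evaluates in closed form to
    (e^y - 1) * omega^4 (15 sigma + 4 omega) / (120 sigma^2).
    """
    sigma, omega = model.sigma, model.omega
    return 4 * math.pi * math.expm1(y) * omega**4 * (15 * sigma + 4 * omega) / (120 * sigma**2)


def association_strength(
    temperature: float, eta: float, model: ProteinModel, eps: float
) -> float:
    """Sticky-limit association strength Delta_AB in nm^3.

    Delta = g_hs(sigma) * 4*pi*Int_sigma^{sigma+omega} fbar(r) r^2 dr.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    return ghs_contact(eta) * _bond_volume(model, eps / temperature)


def monomer_fraction(rho: float, delta: float, n_sites: int) -> float:
    """Fraction X of sites unbonded, from X + (M rho Delta) X^2 = 1.

    Closed-form positive root, written in the cancellation-free form
    X = 2 / (1 + sqrt(1 + 4 kappa)) with kappa = M rho Delta.
    """
    if rho < 0 or delta < 0:
        raise ValueError("rho and delta must be >= 0")
    kappa = n_sites * rho * delta
    return 2.0 / (1.0 + math.sqrt(1.0 + 4.0 * kappa))


# ---------------------------------------------------------------------------
# Reduced (eta, y) state functions; shared with the phase solvers
# ---------------------------------------------------------------------------

def _lambda_assoc(model: ProteinModel, y: float) -> float:
    """kappa = lambda * eta * g_hs(eta) with lambda = M * rho(eta=1) * bond volume."""
    return model.n_sites * (6.0 / (math.pi * model.sigma**3)) * _bond_volume(model, y)


def _x_reduced(eta: float, y: float, model: ProteinModel) -> float:
    kappa = _lambda_assoc(model, y) * eta * ghs_contact(eta)
    return 2.0 / (1.0 + math.sqrt(1.0 + 4.0 * kappa))


def _beta_a_reduced(eta: float, y: float, model: ProteinModel) -> float:
    """beta*A/N as a function of (eta, y)."""
    rho = 6.0 * eta / (math.pi * model.sigma**3)
    x = _x_reduced(eta, y, model)
    a_id = math.log(rho * THERMAL_WAVELENGTH_NM**3) - 1.0
    a_hs = eta * (4 - 3 * eta) / (1 - eta) ** 2
    a_ass = model.n_sites * (math.log(x) - x / 2.0 + 0.5)
    return a_id + a_hs + a_ass


def _w_factor(eta: float) -> float:
    """w = 1 + eta * g'(eta)/g(eta) = d ln(eta*g)/d ln eta."""
    return 1.0 + eta * (5 + eta) / ((1 - eta) * (2 + eta))


def _w_prime(eta: float) -> float:
    return (10 + 4 * eta + 4 * eta**2) / (2 - eta - eta**2) ** 2


def _w_second(eta: float) -> float:
    return (28 + 60 * eta + 12 * eta**2 + 8 * eta**3) / (2 - eta - eta**2) ** 3


def _pressure_reduced(eta: float, y: float, model: ProteinModel) -> float:
    """P(eta) = beta*Pi * (pi sigma^3 / 6), i.e. beta*Pi in eta units.

    P = eta * Z with the Carnahan-Starling compressibility factor and the
    TPT1 association term Z_ass = -(M/2)(1-X)(1 + eta g'/g).
    """
    m = model.n_sites
    x = _x_reduced(eta, y, model)
    hs = (4 * eta**2 - 2 * eta**3) / (1 - eta) ** 3
    return eta + hs - (m / 2.0) * eta * (1 - x) * _w_factor(eta)


def _pressure_reduced_d1(eta: float, y: float, model: ProteinModel) -> float:
    """dP/deta, analytic."""
    m = model.n_sites
    lam = _lambda_assoc(model, y)
    g = ghs_contact(eta)
    kappa = lam * eta * g
    s = math.sqrt(1.0 + 4.0 * kappa)
    x = 2.0 / (1.0 + s)
    kp = lam * (g + eta * _ghs_prime(eta))
    xp = -kp * x**2 / s
    w = _w_factor(eta)
    wp = _w_prime(eta)
    hs = (8 * eta - 2 * eta**2) / (1 - eta) ** 4
    return 1.0 + hs - (m / 2.0) * ((1 - x) * w - eta * xp * w + eta * (1 - x) * wp)


def _pressure_reduced_d2(eta: float, y: float, model: ProteinModel) -> float:
    """d^2 P / deta^2, analytic."""
    m = model.n_sites
    lam = _lambda_assoc(model, y)
    g = ghs_contact(eta)
    gp = _ghs_prime(eta)
    gpp = _ghs_second(eta)
    kappa = lam * eta * g
    s = math.sqrt(1.0 + 4.0 * kappa)
    x = 2.0 / (1.0 + s)
    kp = lam * (g + eta * gp)
    kpp = lam * (2 * gp + eta * gpp)
    sp = 2 * kp / s
    xp = -kp * x**2 / s
    xpp = -(kpp * x**2 / s + kp * (2 * x * xp / s - x**2 * sp / s**2))
    w = _w_factor(eta)
    wp = _w_prime(eta)
    wpp = _w_second(eta)
    hs = (8 + 20 * eta - 4 * eta**2) / (1 - eta) ** 5
    q_prime = (
        -2 * xp * w
        + 2 * (1 - x) * wp
        - eta * xpp * w
        - 2 * eta * xp * wp
        + eta * (1 - x) * wpp
    )
    return hs - (m / 2.0) * q_prime


def _mu_reduced(eta: float, y: float, model: ProteinModel) -> float:
    """beta*mu = beta*A/N + beta*Pi/rho."""
    return _beta_a_reduced(eta, y, model) + _pressure_reduced(eta, y, model) / eta


# ---------------------------------------------------------------------------
# Public physical-unit state functions
# ---------------------------------------------------------------------------

def free_energy(
    rho: float, temperature: float, model: ProteinModel, eps: float
) -> ThermoEvaluation:
    """Helmholtz free-energy parts (beta*A/N) and monomer fraction at one state."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    if rho <= 0:
        raise ValueError(f"number density must be > 0, got {rho}")
    eta = packing_fraction(rho, model.sigma)
    y = eps / temperature
    x = _x_reduced(eta, y, model)
    a_id = math.log(rho * THERMAL_WAVELENGTH_NM**3) - 1.0
    a_hs = eta * (4 - 3 * eta) / (1 - eta) ** 2
    a_ass = model.n_sites * (math.log(x) - x / 2.0 + 0.5)
    return ThermoEvaluation(
        monomer_fraction=x,
        beta_a_ideal=a_id,
        beta_a_hs=a_hs,
        beta_a_assoc=a_ass,
    )


def osmotic_pressure(
    rho: float, temperature: float, model: ProteinModel, eps: float
) -> float:
    """beta*Pi in nm^-3, by analytic differentiation of the free energy."""
    eta = packing_fraction(rho, model.sigma)
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    c = 6.0 / (math.pi * model.sigma**3)
    return c * _pressure_reduced(eta, eps / temperature, model)


def chemical_potential(
    rho: float, temperature: float, model: ProteinModel, eps: float
) -> float:
    """beta*mu (dimensionless); satisfies beta*mu = beta*A/N + beta*Pi/rho."""
    if rho <= 0:
        raise ValueError(f"number density must be > 0, got {rho}")
    eta = packing_fraction(rho, model.sigma)
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    return _mu_reduced(eta, eps / temperature, model)


def evaluate_state(
    rho: float, temperature: float, model: ProteinModel, eps: float
) -> ThermoEvaluation:
    """Free-energy parts plus beta*Pi and beta*mu at one (rho, T, eps)."""
    parts = free_energy(rho, temperature, model, eps)
    return ThermoEvaluation(
        monomer_fraction=parts.monomer_fraction,
        beta_a_ideal=parts.beta_a_ideal,
        beta_a_hs=parts.beta_a_hs,
        beta_a_assoc=parts.beta_a_assoc,
        beta_pressure=osmotic_pressure(rho, temperature, model, eps),
        beta_mu=chemical_potential(rho, temperature, model, eps),
    )


def second_virial(temperature: float, model: ProteinModel, eps: float) -> SecondVirial:
    """Second virial coefficient B2 (nm^3) and B22 (mol mL / g^2).

    B2 = 2*pi*sigma^3/3 - (M^2/2) * 4*pi*Int fbar(r) r^2 dr: the hard-sphere
    part plus the low-density limit of the M x M site-pair attractions.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    b2_hs = 2 * math.pi * model.sigma**3 / 3.0
    b2 = b2_hs - (model.n_sites**2 / 2.0) * _bond_volume(model, eps / temperature)
    b22 = b2 * AVOGADRO * ML_PER_NM3 / model.molar_mass**2
    return SecondVirial(b2_nm3=b2, b22_mol_ml_g2=b22)


def epsilon_at_ionic_strength(buffer: BufferInteraction, ionic_strength: float) -> float:
    """Effective well depth epsilon(I) = eps0 + a*sqrt(I), in K."""
    return buffer.epsilon(ionic_strength)
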