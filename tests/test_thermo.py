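"""TPT1 state functions against brute-force and analytic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import bisect

from patchyllps import (
    association_strength,
    chemical_potential,
    evaluate_state,
    free_energy,
    ghs_contact,
    mayer_angular_average,
    monomer_fraction,
    osmotic_pressure,
    pair_boltzmann_config_energy,
    second_virial,
)
from patchyllps.models import density_from_packing


def mc_mayer_average(r, temperature, eps, model, n, rng):
    """Brute-force orientation average of exp(-beta*u_AB) - 1 for one site pair.

    Samples independent uniform site orientations on both spheres and uses
    the indicator of site-site contact; returns the mean of
    (e^{beta eps} - 1) * indicator. Contact probabilities are small, so the
    caller should compute the z-score with the standard error under the
    null hypothesis rather than the (zero-inflated) sample estimate.
    """
    d = model.site_distance
    u1 = rng.normal(size=(n, 3))
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    u2 = rng.normal(size=(n, 3))
    u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
    sep = d * u2 + np.array([0.0, 0.0, r]) - d * u1
    hit = np.linalg.norm(sep, axis=1) <= model.omega
    boltz = math.expm1(eps / temperature)
    return boltz * float(hit.mean())


def mc_standard_error(closed_value, temperature, eps, n):
    """SE of the MC Mayer-average estimator under the closed-form null."""
    boltz = math.expm1(eps / temperature)
    p = closed_value / boltz
    return boltz * math.sqrt(p * (1 - p) / n)


class TestPercusYevickContact:
    def test_ideal_gas_limit(self):
        assert ghs_contact(0.0) == 1.0

    def test_hewl_90_mg_ml(self):
        assert ghs_contact(0.0801) == pytest.approx(1.2290, abs=2e-4)

    def test_monotone(self):
        assert ghs_contact(0.2) > ghs_contact(0.1) > ghs_contact(0.05)

    def test_domain(self):
        with pytest.raises(ValueError):
            ghs_contact(-0.1)
        with pytest.raises(ValueError):
            ghs_contact(1.0)


class TestPairEnergy:
    def test_beyond_site_reach(self, hewl):
        z = np.array([[0.0, 0.0, 1.0]])
        assert pair_boltzmann_config_energy(2 * hewl.sigma, z, -z, hewl, 2000.0) == 0.0

    def test_hard_overlap(self, hewl):
        z = np.array([[0.0, 0.0, 1.0]])
        assert pair_boltzmann_config_energy(0.9 * hewl.sigma, z, -z, hewl, 2000.0) == math.inf

    def test_head_on_contact(self, hewl):
        # facing sites at r = sigma + omega/2: site gap = omega/2 <= omega
        z = np.array([[0.0, 0.0, 1.0]])
        r = hewl.sigma + hewl.omega / 2
        assert pair_boltzmann_config_energy(r, z, -z, hewl, 2000.0) == -2000.0

    def test_single_bond_rule(self, hewl):
        # two coincident sites on each sphere could form four geometric
        # contacts but at most min(2, 2) = 2 bonds are allowed
        z = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        r = hewl.sigma + hewl.omega / 2
        assert pair_boltzmann_config_energy(r, z, -z, hewl, 2000.0) == -2 * 2000.0


class TestMayerAverage:
    def test_null_well(self, hewl):
        for r in (hewl.sigma, hewl.sigma + hewl.omega / 2):
            assert mayer_angular_average(r, 300.0, 0.0, hewl) == 0.0

    def test_geometric_cutoff(self, hewl):
        assert mayer_angular_average(hewl.sigma + hewl.omega + 0.01, 300.0, 2000.0, hewl) == 0.0

    def test_below_contact_rejected(self, hewl):
        with pytest.raises(ValueError):
            mayer_angular_average(0.99 * hewl.sigma, 300.0, 2000.0, hewl)

    def test_monotone_in_eps_and_temperature(self, hewl):
        r = hewl.sigma + hewl.omega / 2
        assert mayer_angular_average(r, 300.0, 2500.0, hewl) > mayer_angular_average(
            r, 300.0, 2000.0, hewl
        )
        assert mayer_angular_average(r, 280.0, 2000.0, hewl) > mayer_angular_average(
            r, 320.0, 2000.0, hewl
        )

    @pytest.mark.parametrize("frac", [0.1, 0.5, 0.8])
    def test_matches_mc_orientation_average(self, hewl, frac):
        r = hewl.sigma + frac * hewl.omega
        n = 400_000
        rng = np.random.default_rng(42)
        mc = mc_mayer_average(r, 300.0, 2000.0, hewl, n, rng)
        closed = mayer_angular_average(r, 300.0, 2000.0, hewl)
        assert abs(closed - mc) <= 3 * mc_standard_error(closed, 300.0, 2000.0, n)


class TestAssociationStrength:
    def test_null_well(self, hewl):
        assert association_strength(300.0, 0.1, hewl, 0.0) == 0.0

    def test_contact_value_factorization(self, hewl):
        # Delta = g_hs(sigma) * (radial integral): the eta dependence is
        # exactly the PY contact value
        ratio = association_strength(300.0, 0.2, hewl, 2000.0) / association_strength(
            300.0, 0.1, hewl, 2000.0
        )
        assert ratio == pytest.approx(ghs_contact(0.2) / ghs_contact(0.1), rel=1e-12)

    def test_monotone_in_eps_and_eta(self, hewl):
        assert association_strength(300.0, 0.08, hewl, 2500.0) > association_strength(
            300.0, 0.08, hewl, 2000.0
        )
        assert association_strength(300.0, 0.2, hewl, 2000.0) > association_strength(
            300.0, 0.1, hewl, 2000.0
        )

    def test_matches_radial_quadrature(self, hewl):
        # independent adaptive quadrature of 4*pi*r^2*fbar(r) over [sigma, sigma+omega]
        t, eps, eta = 300.0, 2000.0, 0.08
        integral, err = quad(
            lambda r: 4 * math.pi * r**2 * mayer_angular_average(r, t, eps, hewl),
            hewl.sigma,
            hewl.sigma + hewl.omega,
            epsabs=0,
            epsrel=1e-12,
        )
        expected = ghs_contact(eta) * integral
        assert association_strength(t, eta, hewl, eps) == pytest.approx(expected, rel=1e-8)


class TestMonomerFraction:
    def test_no_bonding(self):
        assert monomer_fraction(0.003, 0.0, 10) == 1.0

    def test_golden_ratio_point(self):
        # M*rho*Delta = 1: X + X^2 = 1 has root (sqrt(5)-1)/2
        x = monomer_fraction(1.0, 0.1, 10)
        assert x == pytest.approx((math.sqrt(5) - 1) / 2, rel=1e-12)

    def test_strong_bonding_limit(self):
        xs = [monomer_fraction(1.0, d, 10) for d in (1.0, 10.0, 100.0, 1e6)]
        assert all(b < a for a, b in zip(xs, xs[1:]))
        assert xs[-1] < 1e-3

    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    def test_in_unit_interval(self, rho, delta):
        assert 0 < monomer_fraction(rho, delta, 10) <= 1


class TestFreeEnergy:
    def test_null_well_reduces_to_hard_sphere(self, hewl):
        ev = free_energy(3e-3, 280.0, hewl, 0.0)
        assert ev.beta_a_assoc == 0.0
        assert ev.monomer_fraction == 1.0

    def test_dilute_limit(self, hewl):
        ev = free_energy(1e-9, 280.0, hewl, 2000.0)
        assert abs(ev.beta_a_hs) < 1e-7
        assert ev.monomer_fraction == pytest.approx(1.0, abs=1e-6)

    def test_association_term_consistent_with_bisected_x(self, hewl):
        # re-derive X by bisection of the mass-action law, then evaluate the
        # association free energy M*(ln X - X/2 + 1/2) independently
        eta, t, eps = 0.08, 280.0, 2250.0
        rho = density_from_packing(eta, hewl.sigma)
        delta = association_strength(t, eta, hewl, eps)
        x = bisect(
            lambda x_: x_ + hewl.n_sites * rho * delta * x_**2 - 1.0,
            1e-12, 1.0, xtol=1e-15,
        )
        expected = hewl.n_sites * (math.log(x) - x / 2 + 0.5)
        ev = free_energy(rho, t, hewl, eps)
        assert ev.beta_a_assoc == pytest.approx(expected, abs=1e-12)
        assert ev.monomer_fraction == pytest.approx(x, abs=1e-12)

    @given(
        st.floats(1e-4, 0.45),
        st.floats(200.0, 400.0),
        st.floats(0.0, 3000.0),
    )
    def test_association_free_energy_nonpositive(self, hewl, eta, t, eps):
        rho = density_from_packing(eta, hewl.sigma)
        assert free_energy(rho, t, hewl, eps).beta_a_assoc <= 0.0


class TestPressureAndChemicalPotential:
    def test_ideal_gas_limit(self, hewl):
        rho = 1e-9
        assert osmotic_pressure(rho, 300.0, hewl, 0.0) / rho == pytest.approx(1.0, rel=1e-7)

    def test_carnahan_starling_compressibility(self, hewl):
        # hard spheres at eta=0.3: Z = (1+eta+eta^2-eta^3)/(1-eta)^3 = 3.9738
        rho = density_from_packing(0.3, hewl.sigma)
        z = osmotic_pressure(rho, 300.0, hewl, 0.0) / rho
        assert z == pytest.approx(3.9738, abs=2e-4)

    def test_matches_finite_difference_of_free_energy(self, hewl):
        eta, t, eps = 0.08, 280.0, 2250.0
        rho = density_from_packing(eta, hewl.sigma)
        h = 1e-5 * rho
        a = lambda r: free_energy(r, t, hewl, eps).beta_a_total
        dad_rho = (a(rho + h) - a(rho - h)) / (2 * h)
        pi_fd = rho**2 * dad_rho
        assert osmotic_pressure(rho, t, hewl, eps) == pytest.approx(pi_fd, rel=1e-7)
        mu_fd = a(rho) + pi_fd / rho
        assert chemical_potential(rho, t, hewl, eps) == pytest.approx(mu_fd, rel=1e-7)

    @given(
        st.floats(1e-4, 0.45),
        st.floats(200.0, 400.0),
        st.floats(0.0, 2800.0),
    )
    def test_gibbs_duhem(self, hewl, eta, t, eps):
        rho = density_from_packing(eta, hewl.sigma)
        ev = evaluate_state(rho, t, hewl, eps)
        assert abs(ev.beta_mu - ev.beta_a_total - ev.beta_pressure / rho) < 1e-10

    def test_dilute_side_pressure_positive(self, hewl):
        for gamma in (1.0, 10.0, 50.0):
            rho = hewl.number_density(gamma)
            assert osmotic_pressure(rho, 300.0, hewl, 2000.0) > 0


class TestSecondVirial:
    def test_hard_sphere_limit(self, hewl):
        sv = second_virial(300.0, hewl, 0.0)
        assert sv.b2_nm3 == pytest.approx(2 * math.pi * 3.43**3 / 3, rel=1e-12)
        assert sv.b2_nm3 == pytest.approx(84.51, abs=0.01)
        assert sv.b22_mol_ml_g2 == pytest.approx(2.49e-4, rel=2e-3)

    def test_monotone_decreasing_in_eps(self, hewl):
        b2s = [second_virial(298.0, hewl, e).b2_nm3 for e in (0.0, 1000.0, 2000.0, 2500.0)]
        assert all(b < a for a, b in zip(b2s, b2s[1:]))

    def test_high_temperature_limit(self, hewl):
        hs = second_virial(300.0, hewl, 0.0).b2_nm3
        assert second_virial(1e7, hewl, 2000.0).b2_nm3 == pytest.approx(hs, rel=1e-3)

    def test_matches_virial_limit_of_pressure(self, hewl):
        t, eps = 298.0, 2000.0
        def slope(rho):
            return (osmotic_pressure(rho, t, hewl, eps) / rho - 1.0) / rho
        # Richardson extrapolation to rho -> 0 from rho = 1e-6 and 1e-7
        f1, f2 = slope(1e-6), slope(1e-7)
        extrap = (10 * f2 - f1) / 9
        assert extrap == pytest.approx(second_virial(t, hewl, eps).b2_nm3, rel=1e-3)
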