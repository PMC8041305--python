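"""Phase-equilibrium solvers against grid oracles and known orderings."""

import math

import numpy as np
import pytest

from patchyllps import (
    PhaseSolverError,
    binodal_curve,
    cloud_point_for_epsilon,
    cloud_point_temperature,
    coexistence_at_temperature,
    critical_point,
    fit_eps0,
    osmotic_pressure,
    spinodal_densities,
)
from patchyllps.models import ProteinModel, density_from_packing
from patchyllps.thermo import _beta_a_reduced


def common_tangent_oracle(temperature, model, eps, n_grid=30_000):
    """Independent grid construction of the coexistence densities.

    Builds beta*A/V on a dense packing-fraction grid, takes the lower convex
    hull (monotone chain), and reads the tie line off the hull edge that
    skips grid points. Accuracy is limited by the grid spacing only.
    """
    y = eps / temperature
    eta = np.unique(
        np.concatenate(
            [np.geomspace(1e-5, 0.6, n_grid // 2), np.linspace(1e-5, 0.6, n_grid // 2)]
        )
    )
    f = np.array([e * _beta_a_reduced(e, y, model) for e in eta])
    hull = []
    for i in range(len(eta)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (eta[i2] - eta[i1]) * (f[i] - f[i1]) - (eta[i] - eta[i1]) * (
                f[i2] - f[i1]
            )
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    gaps = np.diff(hull)
    k = int(np.argmax(gaps))
    e1, e2 = eta[hull[k]], eta[hull[k + 1]]
    return (
        density_from_packing(e1, model.sigma),
        density_from_packing(e2, model.sigma),
    )


class TestSpinodal:
    def test_none_above_critical(self, hewl):
        t_c, _ = critical_point(hewl, 2250.0)
        assert spinodal_densities(t_c * 1.2, hewl, 2250.0) is None

    def test_zero_pressure_slope_at_roots(self, hewl):
        t = 250.0
        lo, hi = spinodal_densities(t, hewl, 2250.0)
        for rho in (lo, hi):
            h = 1e-7 * rho
            slope = (
                osmotic_pressure(rho + h, t, hewl, 2250.0)
                - osmotic_pressure(rho - h, t, hewl, 2250.0)
            ) / (2 * h)
            assert abs(slope) < 1e-9
        assert lo < hi

    def test_binodal_straddles_spinodal(self, hewl):
        t = 250.0
        s_lo, s_hi = spinodal_densities(t, hewl, 2250.0)
        cx = coexistence_at_temperature(t, hewl, 2250.0)
        assert cx.rho_dilute < s_lo < s_hi < cx.rho_dense


class TestCriticalPoint:
    def test_ordering_in_eps(self, hewl):
        t_low, _ = critical_point(hewl, 1940.0)
        t_high, _ = critical_point(hewl, 2250.0)
        assert t_high > t_low

    def test_energy_scaling_invariance(self, hewl):
        # dimensionless state functions depend on (T, eps) only through eps/T,
        # so T_c is proportional to eps
        t1, r1 = critical_point(hewl, 2000.0)
        t2, r2 = critical_point(hewl, 2500.0)
        assert t1 / 2000.0 == pytest.approx(t2 / 2500.0, rel=1e-12)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_simple_critical_point(self, hewl):
        # third density derivative of beta*Pi must be nonzero at (T_c, rho_c)
        t_c, rho_c = critical_point(hewl, 2250.0)
        h = 5e-3 * rho_c
        pi = lambda r: osmotic_pressure(r, t_c, hewl, 2250.0)
        d3 = (
            pi(rho_c + 2 * h) - 2 * pi(rho_c + h) + 2 * pi(rho_c - h) - pi(rho_c - 2 * h)
        ) / (2 * h**3)
        assert abs(d3) * rho_c**2 > 1e-3  # scaled to O(1) units

    def test_residuals(self, hewl):
        t_c, rho_c = critical_point(hewl, 2250.0)
        h = 2e-5 * rho_c
        pi = lambda r: osmotic_pressure(r, t_c, hewl, 2250.0)
        d1 = (pi(rho_c + h) - pi(rho_c - h)) / (2 * h)
        assert abs(d1) < 1e-9


class TestCoexistence:
    def test_defining_residuals(self, hewl):
        t_c, _ = critical_point(hewl, 2250.0)
        cx = coexistence_at_temperature(0.9 * t_c, hewl, 2250.0)
        assert max(abs(r) for r in cx.residuals) < 1e-8

    def test_near_critical_closure(self, hewl):
        t_c, rho_c = critical_point(hewl, 2250.0)
        cx = coexistence_at_temperature(0.999 * t_c, hewl, 2250.0)
        assert cx.rho_dilute == pytest.approx(rho_c, rel=0.2)
        assert cx.rho_dense == pytest.approx(rho_c, rel=0.2)
        assert cx.rho_dilute < rho_c < cx.rho_dense

    def test_above_critical_rejected(self, hewl):
        t_c, _ = critical_point(hewl, 2250.0)
        with pytest.raises(ValueError):
            coexistence_at_temperature(t_c * 1.01, hewl, 2250.0)

    @pytest.mark.parametrize("frac", [0.95, 0.97, 0.99])
    def test_matches_common_tangent_oracle(self, hewl, frac):
        t_c, _ = critical_point(hewl, 2250.0)
        t = frac * t_c
        cx = coexistence_at_temperature(t, hewl, 2250.0)
        o_lo, o_hi = common_tangent_oracle(t, hewl, 2250.0)
        assert cx.rho_dilute == pytest.approx(o_lo, rel=1e-3)
        assert cx.rho_dense == pytest.approx(o_hi, rel=1e-3)


class TestBinodalCurve:
    def test_dome_shape_and_monotone_branches(self, hewl):
        curve = binodal_curve(hewl, 2250.0, n_temperatures=25)
        temps = [p.temperature for p in curve.points]
        assert max(temps) < curve.critical_temperature
        assert temps == sorted(temps)
        dilute = [p.rho_dilute for p in curve.points]
        dense = [p.rho_dense for p in curve.points]
        # dilute branch shrinks and dense branch grows on cooling
        assert all(a < b for a, b in zip(dilute, dilute[1:]))
        assert all(a > b for a, b in zip(dense, dense[1:]))
        assert all(p.rho_dilute < curve.critical_density < p.rho_dense for p in curve.points)

    def test_deterministic(self, hewl):
        a = binodal_curve(hewl, 2140.0, n_temperatures=12)
        b = binodal_curve(hewl, 2140.0, n_temperatures=12)
        assert a == b

    def test_buffer_dome_ordering(self, hewl, buffers):
        # zero-salt dome heights follow eps0: phosphate (least stable, highest
        # dome) > HEPES > MOPS > cacodylate (most stable)
        tcs = {
            name: binodal_curve(hewl, buf.eps0, n_temperatures=5).critical_temperature
            for name, buf in buffers.items()
        }
        assert tcs["phosphate"] > tcs["HEPES"] > tcs["MOPS"] > tcs["cacodylate"]

    def test_dome_broadens_with_fewer_sites(self, hewl):
        # at fixed reduced temperature the coexistence region widens as the
        # bonding valence M drops (fewer, more directional contacts)
        wide = {}
        for m_sites in (6, 10):
            model = ProteinModel(
                sigma=hewl.sigma,
                omega=hewl.omega,
                n_sites=m_sites,
                molar_mass=hewl.molar_mass,
            )
            t_c, rho_c = critical_point(model, 2250.0)
            cx = coexistence_at_temperature(0.92 * t_c, model, 2250.0)
            wide[m_sites] = (cx.rho_dense - cx.rho_dilute) / rho_c
        assert wide[6] > wide[10]


class TestCloudPoint:
    def test_round_trip_on_binodal(self, hewl):
        curve = binodal_curve(hewl, 2250.0, n_temperatures=10, t_min_fraction=0.92)
        for p in curve.points:
            gamma = hewl.mass_concentration(p.rho_dilute)
            t = cloud_point_for_epsilon(gamma, hewl, 2250.0)
            assert t == pytest.approx(p.temperature, abs=2e-3)

    def test_concentration_ordering(self, hewl, buffers):
        for buf in buffers.values():
            t90 = cloud_point_temperature(90.0, hewl, buf, 0.0)
            t125 = cloud_point_temperature(125.0, hewl, buf, 0.0)
            assert t125 > t90

    def test_salting_out_direction(self, hewl, buffers):
        buf = buffers["MOPS"]
        ts = [cloud_point_temperature(90.0, hewl, buf, i) for i in (0.0, 0.1, 0.3, 0.5)]
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_critical_concentration_returns_tc(self, hewl):
        t_c, rho_c = critical_point(hewl, 2250.0)
        gamma_c = hewl.mass_concentration(rho_c)
        assert cloud_point_for_epsilon(gamma_c, hewl, 2250.0) == pytest.approx(
            t_c, abs=1e-6
        )

    def test_dense_branch_crossing(self, hewl):
        # concentrations right of the dome apex cross on the dense branch
        t = cloud_point_for_epsilon(400.0, hewl, 2250.0)
        t_c, _ = critical_point(hewl, 2250.0)
        cx = coexistence_at_temperature(t, hewl, 2250.0)
        assert t < t_c
        assert hewl.mass_concentration(cx.rho_dense) == pytest.approx(400.0, rel=1e-6)

    def test_unreachable_concentration_rejected(self, hewl):
        with pytest.raises((PhaseSolverError, ValueError)):
            cloud_point_for_epsilon(660.0, hewl, 2250.0)


class TestFitEps0RoundTrip:
    def test_identity_across_depths(self, hewl):
        for eps in (1800.0, 2100.0, 2400.0):
            t = cloud_point_for_epsilon(90.0, hewl, eps)
            assert fit_eps0(hewl, 90.0, t) == pytest.approx(eps, abs=0.1)
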