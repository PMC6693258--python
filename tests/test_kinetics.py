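"""Clipped-linear kinetics: synthesis clamps, fixed point, linear stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rdscales as rd
from rdscales.kinetics import SingularKineticsError


@pytest.fixture
def p():
    return rd.KineticParams.reference()


class TestSynthesis:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            (0.0, 0.0, 0.015),  # basal rate, clamp inactive
            (10.0, 0.0, 0.19),  # 0.615 saturates at F_max
            (0.0, 10.0, 0.0),  # -0.685 floored at zero
        ],
    )
    def test_activator_synthesis(self, p, u, v, expected):
        assert rd.synthesis_u(u, v, p) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "u, v, expected",
        [
            (0.0, 0.0, 0.0),  # c_v < 0 floored
            (10.0, 0.0, 0.184),  # 0.583 saturates at G_max
            (1.0, 1.0, 0.0398),  # inside the band: linear arithmetic
        ],
    )
    def test_inhibitor_synthesis(self, p, u, v, expected):
        assert rd.synthesis_v(u, v, p) == pytest.approx(expected, abs=1e-15)

    def test_elementwise_on_grids(self, p):
        u = np.array([[0.0, 10.0], [0.0, 1.0]])
        v = np.array([[0.0, 0.0], [10.0, 1.0]])
        np.testing.assert_allclose(
            rd.synthesis_u(u, v, p), [[0.015, 0.19], [0.0, 0.06 - 0.07 + 0.015]]
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        u=st.floats(-1e6, 1e6, allow_nan=False),
        v=st.floats(-1e6, 1e6, allow_nan=False),
    )
    def test_synthesis_always_inside_clip_bands(self, u, v):
        p = rd.KineticParams.reference()
        assert 0.0 <= rd.synthesis_u(u, v, p) <= p.F_max
        assert 0.0 <= rd.synthesis_v(u, v, p) <= p.G_max


class TestReaction:
    def test_origin(self, p):
        ru, rv = rd.reaction(0.0, 0.0, p)
        assert ru == pytest.approx(0.015) and rv == 0.0

    def test_both_syntheses_capped(self, p):
        ru, rv = rd.reaction(100.0, 0.0, p)
        assert ru == pytest.approx(0.19 - 2.0)
        assert rv == pytest.approx(0.184)

    def test_vanishes_at_fixed_point(self, p):
        fp = rd.homogeneous_fixed_point(p)
        ru, rv = rd.reaction(fp.u_star, fp.v_star, p)
        assert abs(ru) < 1e-10 and abs(rv) < 1e-10


class TestFixedPoint:
    def test_matches_cramer_rule_oracle(self, p):
        # independent 2x2 solve of the unclipped balance by Cramer's rule
        a11, a12 = p.a_u - p.d_u, p.b_u
        a21, a22 = p.a_v, p.b_v - p.d_v
        det = a11 * a22 - a12 * a21
        u_star = (-p.c_u * a22 + p.c_v * a12) / det
        v_star = (-p.c_v * a11 + p.c_u * a21) / det
        fp = rd.homogeneous_fixed_point(p)
        assert fp.u_star == pytest.approx(u_star, abs=1e-12)
        assert fp.v_star == pytest.approx(v_star, abs=1e-12)
        assert fp.u_star == pytest.approx(0.67853, abs=1e-5)
        assert fp.v_star == pytest.approx(0.60201, abs=1e-5)
        assert fp.in_linear_regime
        # both synthesis terms strictly inside their clip bands
        assert 0 < rd.synthesis_u(fp.u_star, fp.v_star, p) < p.F_max
        assert 0 < rd.synthesis_v(fp.u_star, fp.v_star, p) < p.G_max

    def test_decoupled_activator_balances_basal_rate(self, p):
        q = p.replace(a_u=0.0, b_u=0.0, c_u=0.02, d_u=0.02)
        assert rd.homogeneous_fixed_point(q).u_star == pytest.approx(1.0)

    def test_singular_balance_raises(self, p):
        q = p.replace(b_u=0.0, a_u=p.d_u)  # zero first row -> det 0
        with pytest.raises(SingularKineticsError):
            rd.homogeneous_fixed_point(q)

    def test_saturated_regime_found_by_bounded_search(self, p):
        # Cap activator synthesis below its value at the linear balance point:
        # the clipped fixed point has F pinned at F_max, so u* = F_max/d_u = 0.5,
        # and v* solves a_v u* + b_v v + c_v = d_v v  ->  v* = 0.2.
        q = p.replace(F_max=0.01)
        fp = rd.homogeneous_fixed_point(q)
        assert not fp.in_linear_regime
        assert fp.u_star == pytest.approx(0.01 / 0.02, abs=1e-8)
        assert fp.v_star == pytest.approx(0.2, abs=1e-8)
        ru, rv = rd.reaction(fp.u_star, fp.v_star, q)
        assert abs(ru) < 1e-10 and abs(rv) < 1e-10


class TestDispersionRelation:
    def test_k0_matches_quadratic_formula_oracle(self, p):
        # eigenvalues of the 2x2 Jacobian via the characteristic polynomial
        tr = (p.a_u - p.d_u) + (p.b_v - p.d_v)
        det = (p.a_u - p.d_u) * (p.b_v - p.d_v) - p.b_u * p.a_v
        disc = complex(tr * tr - 4 * det)
        lam = (tr + np.sqrt(disc)) / 2
        l1, l2 = rd.dispersion_relation(p, 0.0)
        assert l1 == pytest.approx(lam, abs=1e-12)
        assert l1 == pytest.approx(0.0065 + 0.05598j, abs=1e-5)
        assert l2 == pytest.approx(0.0065 - 0.05598j, abs=1e-5)

    def test_homogeneous_mode_oscillatory_unstable(self, p):
        # pattern containment comes from the clip bounds, not from the
        # textbook Turing condition of k=0 stability
        l1, _ = rd.dispersion_relation(p, 0.0)
        assert l1.real > 0
        assert l1.imag != 0

    def test_turing_band_outgrows_homogeneous_mode(self, p):
        growth = [max(l.real for l in rd.dispersion_relation(p, k)) for k in (0.0, 0.79)]
        assert growth[1] > growth[0] > 0

    def test_diffusive_damping_dominates_large_k(self, p):
        l1, l2 = rd.dispersion_relation(p, 50.0)
        # both branches pinned negative by -k^2 D: ~ -k^2 D_u and -k^2 D_v
        assert l1.real < -40 and l2.real < -900

    def test_decoupled_system_is_triangular(self, p):
        q = p.replace(b_u=0.0, a_v=0.0, a_u=0.01, c_v=0.025)
        k = 0.3
        l1, l2 = rd.dispersion_relation(q, k)
        expected = sorted(
            [q.a_u - q.d_u - k * k * q.D_u, q.b_v - q.d_v - k * k * q.D_v],
            reverse=True,
        )
        assert l1 == pytest.approx(expected[0], abs=1e-14)
        assert l2 == pytest.approx(expected[1], abs=1e-14)

    def test_requires_linear_regime(self, p):
        with pytest.raises(ValueError, match="linear"):
            rd.dispersion_relation(p.replace(F_max=0.01), 0.5)


class TestBoundednessOfHomogeneousODE:
    def test_trajectories_stay_in_invariant_box(self, p):
        # capped synthesis + linear decay confine u to [0, F_max/d_u] and
        # v to [0, G_max/d_v]; integrate the spatially uniform ODE by small
        # Euler steps from the box corners
        u_hi, v_hi = p.F_max / p.d_u, p.G_max / p.d_v
        for u0, v0 in [(0, 0), (u_hi, 0), (0, v_hi), (u_hi, v_hi), (1.0, 1.0)]:
            u, v = float(u0), float(v0)
            dt = 0.05
            for _ in range(20_000):
                ru, rv = rd.reaction(u, v, p)
                u, v = u + dt * ru, v + dt * rv
            assert -1e-9 <= u <= u_hi + 1e-9
            assert -1e-9 <= v <= v_hi + 1e-9


class TestParamsValidationAndSerialisation:
    def test_round_trip_uses_symbol_names(self, p):
        d = p.to_dict()
        assert set(d) == {
            "d_u", "D_u", "a_u", "b_u", "c_u", "F_max",
            "d_v", "D_v", "a_v", "b_v", "c_v", "G_max",
        }
        assert rd.KineticParams.from_dict(d) == p

    @pytest.mark.parametrize(
        "bad", [{"d_u": -0.1}, {"d_v": 0.0}, {"D_u": -1.0}, {"F_max": 0.0}, {"G_max": -2}]
    )
    def test_invalid_parameters_rejected(self, p, bad):
        with pytest.raises(ValueError):
            p.replace(**bad)

    def test_unknown_key_rejected(self, p):
        with pytest.raises(KeyError):
            rd.KineticParams.from_dict({**p.to_dict(), "gamma": 1.0})
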