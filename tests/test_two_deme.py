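"""Two-deme solver, deme-specific indices, negativity threshold, F_ST*, D*."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrightgst import (
    ScaledTwoDemeParams,
    TwoDemeIdentities,
    TwoDemeParams,
    beta_wt0,
    expected_coalescence_times,
    gst0_star,
    hard_migration_partner,
    index_difference,
    is_hard_migration,
    nei_distance_star,
    r_min,
    scale_two_deme,
    slatkin_fst,
    steady_state_identities_twodeme,
)
from wrightgst.two_deme import deme1_view


class TestScaling:
    def test_equal_demes(self):
        sp = scale_two_deme(TwoDemeParams(N0=500, N1=500))
        assert sp.r == 0.5
        assert sp.M0 == sp.M1 == sp.theta == 0.0

    def test_unequal_demes(self):
        sp = scale_two_deme(TwoDemeParams(N0=700, N1=300, m0=1e-3, m1=2e-3, u=5e-4))
        assert sp.r == pytest.approx(0.7)
        assert sp.M0 == pytest.approx(4 * 500 * 1e-3)
        assert sp.M1 == pytest.approx(4 * 500 * 2e-3)
        assert sp.theta == pytest.approx(4 * 500 * 5e-4)

    def test_fast_migration_warns(self):
        with pytest.warns(UserWarning, match="0.15"):
            TwoDemeParams(N0=100, N1=100, m0=0.3)


class TestSteadyStateIdentities:
    def test_unity_without_mutation(self):
        sp = ScaledTwoDemeParams(r=0.4, M0=2.0, M1=1.0, theta=0.0)
        ids = steady_state_identities_twodeme(sp)
        assert (ids.g_w0, ids.g_w1, ids.g_b) == (1.0, 1.0, 1.0)

    def test_symmetry_under_label_exchange(self):
        sp = ScaledTwoDemeParams(r=0.5, M0=1.3, M1=1.3, theta=0.7)
        ids = steady_state_identities_twodeme(sp)
        assert ids.g_w0 == pytest.approx(ids.g_w1, abs=1e-12)

    def test_boundary_case_at_r_min(self):
        # r = 0.7 equals r_min(4, 0.5, 0.5): within-0 and between identities tie
        sp = ScaledTwoDemeParams(r=0.7, M0=4.0, M1=0.5, theta=0.5)
        ids = steady_state_identities_twodeme(sp)
        assert ids.g_w0 == pytest.approx(0.5882352941, abs=1e-9)
        assert ids.g_w1 == pytest.approx(0.7352941176, abs=1e-9)
        assert ids.g_b == pytest.approx(ids.g_w0, abs=1e-12)

    def test_isolated_demes_warn_and_return_zero_between(self):
        sp = ScaledTwoDemeParams(r=0.5, M0=0.0, M1=0.0, theta=1.0)
        with pytest.warns(UserWarning, match="never coalesce"):
            ids = steady_state_identities_twodeme(sp)
        assert ids.g_b == 0.0
        assert ids.g_w0 == pytest.approx(1.0 / 2.0)  # coal rate 1 vs theta 1

    @given(
        r=st.floats(0.05, 0.95),
        M0=st.floats(0.01, 10),
        M1=st.floats(0.01, 10),
        theta=st.floats(0.01, 5),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_identities_lie_in_unit_interval(self, r, M0, M1, theta):
        ids = steady_state_identities_twodeme(
            ScaledTwoDemeParams(r=r, M0=M0, M1=M1, theta=theta))
        for v in (ids.g_w0, ids.g_w1, ids.g_b):
            assert 0.0 < v < 1.0


class TestDemeSpecificIndices:
    @pytest.mark.parametrize("g_w0, g_b, expected", [
        (0.5, 0.5, 0.0), (0.6, 0.5, 0.2), (0.5, 0.6, -0.25),
    ])
    def test_beta_values(self, g_w0, g_b, expected):
        assert beta_wt0(g_w0, g_b) == pytest.approx(expected)

    def test_gst0_values(self):
        assert gst0_star(0.5, 0.5, 0.3) == 0.0
        assert gst0_star(0.6, 0.5, 0.5) == pytest.approx(0.05 / 0.45)

    def test_difference_formula_matches_subtraction(self):
        assert index_difference(0.6, 0.5, 0.5) == pytest.approx(
            beta_wt0(0.6, 0.5) - gst0_star(0.6, 0.5, 0.5), abs=1e-12)

    @given(
        g_w0=st.floats(0.01, 0.99),
        g_b=st.floats(0.01, 0.99),
        r=st.floats(0.01, 0.99),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_sign_agreement_and_dominance(self, g_w0, g_b, r):
        b = beta_wt0(g_w0, g_b)
        g = gst0_star(g_w0, g_b, r)
        assert np.sign(b) == np.sign(g)
        assert abs(b) >= abs(g) - 1e-15
        if g_w0 != g_b:
            assert abs(b) > 0
        assert index_difference(g_w0, g_b, r) == pytest.approx(b - g, abs=1e-12)

    def test_indices_coincide_as_r_vanishes(self):
        assert index_difference(0.6, 0.4, 1e-12) == pytest.approx(0.0, abs=1e-10)


class TestRMin:
    def test_example_value(self):
        assert r_min(4.0, 0.5, 0.5) == pytest.approx(0.7)

    def test_unit_M0_makes_threshold_unreachable(self):
        # at M0 = 1 the threshold is exactly 1 regardless of M1, theta
        for M1, th in ((0.1, 0.1), (3.0, 0.5), (0.0, 2.0)):
            assert r_min(1.0, M1, th) == pytest.approx(1.0)

    def test_large_M0_limit_is_half(self):
        assert r_min(1e9, 0.5, 0.5) == pytest.approx(0.5, abs=1e-8)

    @given(
        M0=st.floats(0.01, 50), M1=st.floats(0.0, 50), theta=st.floats(0.001, 10)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_above_half(self, M0, M1, theta):
        assert r_min(M0, M1, theta) > 0.5

    def test_declines_with_soft_migration(self):
        grid = np.linspace(1.5, 20, 30)
        vals = [r_min(M0, 0.4, 0.3) for M0 in grid]
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("M0, M1, theta", [
        (2.0, 0.2, 0.1), (4.0, 0.5, 0.5), (8.0, 1.0, 0.05),
        (1.5, 0.0, 0.3), (3.0, 2.0, 1.0),
    ])
    def test_matches_solver_boundary(self, M0, M1, theta):
        """Bisection on g_w0 - g_b over r reproduces the closed form."""
        rm = r_min(M0, M1, theta)
        assert 0.5 < rm < 1.0

        def gap(r):
            ids = steady_state_identities_twodeme(
                ScaledTwoDemeParams(r=r, M0=M0, M1=M1, theta=theta))
            return ids.g_w0 - ids.g_b

        lo, hi = 1e-6, 1 - 1e-6
        assert gap(lo) > 0 > gap(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if gap(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(rm, abs=1e-8)


class TestHardMigration:
    def test_partner_values(self):
        assert hard_migration_partner(0.5, 2.0) == pytest.approx(2.0)
        assert hard_migration_partner(0.75, 1.0) == pytest.approx(3.0)

    def test_predicate(self):
        sp = ScaledTwoDemeParams(r=0.75, M0=1.0, M1=3.0, theta=0.2)
        assert is_hard_migration(sp)
        assert not is_hard_migration(
            ScaledTwoDemeParams(r=0.75, M0=1.0, M1=1.0, theta=0.2))

    @pytest.mark.parametrize("r", np.round(np.arange(0.1, 0.95, 0.1), 2).tolist())
    @pytest.mark.parametrize("M0", [0.5, 2.0, 8.0])
    @pytest.mark.parametrize("theta", [0.1, 1.0])
    def test_indices_never_negative(self, r, M0, theta):
        M1 = hard_migration_partner(r, M0)
        ids = steady_state_identities_twodeme(
            ScaledTwoDemeParams(r=r, M0=M0, M1=M1, theta=theta))
        assert beta_wt0(ids.g_w0, ids.g_b) >= -1e-12
        assert gst0_star(ids.g_w0, ids.g_b, r) >= -1e-12


class TestDistanceAndSlatkin:
    def test_distance_zero_iff_no_structure(self):
        assert nei_distance_star(TwoDemeIdentities(0.4, 0.4, 0.4)) == 0.0
        assert nei_distance_star(
            TwoDemeIdentities(0.6, 0.6, 0.3)) == pytest.approx(np.log(2))

    def test_distance_positive_at_any_steady_state(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            r = rng.uniform(0.05, 0.95)
            sp = ScaledTwoDemeParams(
                r=r, M0=rng.uniform(0.05, 8), M1=rng.uniform(0.05, 8),
                theta=rng.uniform(0.05, 4))
            ids = steady_state_identities_twodeme(sp)
            assert nei_distance_star(ids) > 0

    def test_distance_rejects_zero_identity(self):
        with pytest.raises(ValueError):
            nei_distance_star(TwoDemeIdentities(0.5, 0.5, 0.0))

    def test_symmetric_times(self):
        sp = ScaledTwoDemeParams(r=0.5, M0=1.0, M1=1.0, theta=0.0)
        ct = expected_coalescence_times(sp)
        assert ct.E_W0 == pytest.approx(ct.E_W1, abs=1e-12)
        assert ct.E_Ts == pytest.approx(ct.E_W0, abs=1e-12)
        assert slatkin_fst(ct) >= 0

    def test_reducible_chain_rejected(self):
        with pytest.raises(ValueError):
            expected_coalescence_times(
                ScaledTwoDemeParams(r=0.5, M0=0.0, M1=0.0, theta=0.0))

    def test_identical_times_give_zero_index(self):
        from wrightgst import CoalescenceTimes
        ct = CoalescenceTimes(E_W0=1.0, E_W1=1.0, E_B=1.0, E_Ts=1.0, E_T=1.0)
        assert slatkin_fst(ct) == 0.0

    @pytest.mark.parametrize("r, M0, M1", [
        (0.5, 1.0, 1.0), (0.7, 4.0, 0.5), (0.3, 0.5, 2.0),
    ])
    def test_gst_analog_converges_to_slatkin_as_mutation_vanishes(self, r, M0, M1):
        """1 - (1 - g_w-bar)/(1 - g_b-type) style index -> F_ST* as theta -> 0.

        The G-analog is formed from the same pair-sampling weights as E_Ts
        and E_T; for small theta, 1 - g_X ~ theta * E_X.
        """
        ct = expected_coalescence_times(
            ScaledTwoDemeParams(r=r, M0=M0, M1=M1, theta=0.0))
        target = slatkin_fst(ct)
        errs = []
        for theta in (1e-2, 1e-3, 1e-4):
            ids = steady_state_identities_twodeme(
                ScaledTwoDemeParams(r=r, M0=M0, M1=M1, theta=theta))
            w0, w1, wb = r * r, (1 - r) ** 2, 2 * r * (1 - r)
            g_s = (w0 * ids.g_w0 + w1 * ids.g_w1) / (w0 + w1)
            g_t = w0 * ids.g_w0 + w1 * ids.g_w1 + wb * ids.g_b
            index = 1.0 - (1.0 - g_s) / (1.0 - g_t)
            errs.append(abs(index - target))
        assert errs[0] < 0.05
        assert errs[1] < errs[0]
        assert errs[2] < 10 * errs[1]  # rounding floor allowed
        assert errs[2] < 1e-3

    def test_deme1_view_swaps_labels(self):
        sp = ScaledTwoDemeParams(r=0.7, M0=4.0, M1=0.5, theta=0.5)
        ids = steady_state_identities_twodeme(sp)
        ids1 = steady_state_identities_twodeme(deme1_view(sp))
        assert ids1.g_w0 == pytest.approx(ids.g_w1, abs=1e-12)
        assert ids1.g_w1 == pytest.approx(ids.g_w0, abs=1e-12)
        assert ids1.g_b == pytest.approx(ids.g_b, abs=1e-12)
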