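"""Grassi-Magnani partition: sensitivities, identities, published states."""

from dataclasses import replace

import pytest

from photolim import tables
from photolim.errors import DomainError
from photolim.fvcb import FvCBParams, j_light_response, net_assimilation, solve_steady_state
from photolim.limitations import (
    SLOPE_MODES,
    LeafState,
    LimitationResult,
    assimilation_slope,
    partition_limitations,
    total_conductance,
)

HAND = dict(Gamma_star=37.43, K_c=272.0, K_o=165.8, O=210.0)


class TestTotalConductance:
    def test_equal_series_halves(self):
        assert total_conductance(0.1, 0.1) == pytest.approx(0.05, rel=1e-12)

    def test_large_gm_limit(self):
        assert total_conductance(0.21, 1e9) == pytest.approx(0.21, rel=1e-6)

    def test_published_day8_control(self):
        assert total_conductance(0.21, 0.070) == pytest.approx(0.0525, rel=1e-12)

    def test_never_exceeds_either_leg(self):
        g = total_conductance(0.3, 0.04)
        assert g <= min(0.3, 0.04)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            total_conductance(0.0, 0.1)


class TestAssimilationSlope:
    def test_zero_vcmax_gives_zero_rubisco_slope(self):
        ref = LeafState(A_N=5.0, g_sc=0.2, g_m=0.1, V_cmax=1e-12, C_c=150.0)
        p = FvCBParams(V_cmax=1.0, J_max=150.0, R_d=1.0, **HAND)
        assert assimilation_slope(ref, p, mode="rubisco") == pytest.approx(0.0, abs=1e-12)

    def test_rubisco_hand_value(self):
        ref = LeafState(A_N=2.84, g_sc=0.25, g_m=0.074, V_cmax=33.71, C_c=121.43)
        p = FvCBParams(V_cmax=33.71, J_max=144.59, R_d=1.0, **HAND)
        assert assimilation_slope(ref, p, mode="rubisco") == pytest.approx(0.0405, abs=3e-4)

    @pytest.mark.parametrize("mode", SLOPE_MODES)
    def test_matches_finite_difference_of_net_assimilation(self, mode):
        """Each analytic slope equals the central difference of the
        corresponding FvCB expression at h = 0.01 umol/mol."""
        p = FvCBParams(V_cmax=32.62, J_max=148.93, R_d=1.0, **HAND)
        cc = 120.35
        j = j_light_response(1000.0, p.J_max, p.alpha, p.theta)
        # observed A chosen consistent with each target state
        a_c = net_assimilation(cc, p, J=1e9).A_c
        a_j = net_assimilation(cc, p, J=j).A_j
        a_obs = {"rubisco": a_c, "rubp": a_j, "model_min": min(a_c, a_j)}[mode]
        ref = LeafState(A_N=a_obs, g_sc=0.21, g_m=0.07, V_cmax=p.V_cmax, C_c=cc,
                        J_max=p.J_max)
        s = assimilation_slope(ref, p, mode=mode)
        h = 0.01
        if mode == "rubisco" or (mode == "model_min" and a_c <= a_j):
            f = lambda x: net_assimilation(x, p, J=1e9).A_c
        else:
            f = lambda x: net_assimilation(x, p, J=j).A_j
        fd = (f(cc + h) - f(cc - h)) / (2 * h)
        assert s == pytest.approx(fd, rel=1e-6)

    def test_rejects_cc_at_or_below_gamma_star(self):
        ref = LeafState(A_N=1.0, g_sc=0.2, g_m=0.1, V_cmax=30.0, C_c=30.0)
        with pytest.raises(DomainError):
            assimilation_slope(ref, FvCBParams(V_cmax=30.0, J_max=150.0), mode="rubisco")


def _random_state(rng):
    return LeafState(
        A_N=rng.uniform(2, 20),
        g_sc=rng.uniform(0.05, 0.4),
        g_m=rng.uniform(0.02, 0.2),
        V_cmax=rng.uniform(15, 60),
        C_c=rng.uniform(60, 400),
        J_max=rng.uniform(80, 200),
    )


class TestPartition:
    def test_identity_case_all_zero(self):
        p = FvCBParams(V_cmax=33.71, J_max=144.59, R_d=1.0)
        s = tables.leaf_state("stress", 8, "control")
        res = partition_limitations(s, s, p)
        for v in (res.S_L, res.MC_L, res.B_L, res.D_L, res.NS_L, res.T_L):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_sensitivity_coefficients_sum_to_one(self, rng):
        p = FvCBParams(V_cmax=30.0, J_max=150.0, R_d=1.0)
        for _ in range(1000):
            ref = _random_state(rng)
            st_ = _random_state(rng)
            res = partition_limitations(ref, st_, p, mode="rubisco")
            assert abs(res.l_s + res.l_mc + res.l_b - 1.0) < 1e-12
            assert abs(res.D_L - (res.S_L + res.MC_L)) < 1e-9
            assert abs(res.NS_L - (res.MC_L + res.B_L)) < 1e-9
            assert abs(res.T_L - (res.S_L + res.MC_L + res.B_L)) < 1e-9

    def test_mcl_sl_ratio_invariant_to_slope_mode(self):
        p = FvCBParams(V_cmax=33.71, J_max=144.59, R_d=1.0)
        ref = tables.leaf_state("stress", 8, "control")
        st_ = tables.leaf_state("stress", 8, "stress")
        ratios = [
            partition_limitations(ref, st_, p, mode=m).MC_L
            / partition_limitations(ref, st_, p, mode=m).S_L
            for m in SLOPE_MODES
        ]
        assert max(ratios) - min(ratios) < 1e-9
        # the ratio reduces to (g_sc/g_m) * (dgm/gm) / (dgs/gs)
        expected = (0.21 / 0.070) * ((0.070 - 0.037) / 0.070) / ((0.21 - 0.09) / 0.21)
        assert ratios[0] == pytest.approx(expected, rel=1e-9)

    def test_relief_is_flagged_not_clamped(self):
        p = FvCBParams(V_cmax=33.08, J_max=153.75, R_d=1.0)
        ref = tables.leaf_state("recovery", 1, "control")
        st_ = tables.leaf_state("recovery", 1, "recovery")  # g_m above control
        res = partition_limitations(ref, st_, p)
        assert res.MC_L < 0
        assert "MC_L" in res.relief_flags

    def test_log_difference_variant_close_to_fractional_for_small_changes(self):
        p = FvCBParams(V_cmax=30.0, J_max=150.0, R_d=1.0)
        ref = LeafState(A_N=10.0, g_sc=0.2, g_m=0.1, V_cmax=40.0, C_c=200.0, J_max=160.0)
        st_ = LeafState(A_N=9.9, g_sc=0.198, g_m=0.099, V_cmax=39.6, C_c=199.0, J_max=160.0)
        a = partition_limitations(ref, st_, p, relative="fractional")
        b = partition_limitations(ref, st_, p, relative="log")
        assert a.T_L == pytest.approx(b.T_L, rel=0.02)

    def test_converges_to_exact_differential_of_coupled_model(self):
        """1% single-parameter perturbations: each component matches the
        exact relative change of assimilation from the coupled
        steady-state model to within 5% of itself."""
        p = FvCBParams(V_cmax=60.0, J_max=200.0, R_d=0.5)
        ca, g_sc, g_m = 400.0, 0.2, 0.1
        ss = solve_steady_state(ca, g_sc, g_m, p, 1000.0)
        ref = LeafState(A_N=ss.A_N, g_sc=g_sc, g_m=g_m, V_cmax=p.V_cmax,
                        C_c=ss.C_c, J_max=p.J_max)
        eps = 0.01
        cases = {
            "S_L": dict(g_sc=g_sc * (1 - eps), g_m=g_m, p=p),
            "MC_L": dict(g_sc=g_sc, g_m=g_m * (1 - eps), p=p),
            "B_L": dict(g_sc=g_sc, g_m=g_m, p=replace(p, V_cmax=p.V_cmax * (1 - eps))),
        }
        for comp, kw in cases.items():
            ss2 = solve_steady_state(ca, kw["g_sc"], kw["g_m"], kw["p"], 1000.0)
            exact = 100.0 * (ss.A_N - ss2.A_N) / ss.A_N
            st_ = LeafState(A_N=ss2.A_N, g_sc=kw["g_sc"], g_m=kw["g_m"],
                            V_cmax=kw["p"].V_cmax, C_c=ss2.C_c, J_max=p.J_max)
            got = getattr(partition_limitations(ref, st_, p, mode="model_min"), comp)
            assert abs(got - exact) / abs(exact) < 0.05


def test_from_components_builds_consistent_aggregates():
    res = LimitationResult.from_components(11.9, 27.9, 8.0)
    assert res.T_L == pytest.approx(47.8, abs=1e-9)
    assert res.D_L == pytest.approx(39.8, abs=1e-9)
    assert res.NS_L == pytest.approx(35.9, abs=1e-9)
    assert res.relief_flags == ()
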