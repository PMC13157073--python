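"""Kinetic scheme construction, stationary laws and target calibration."""
import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from patchkin import (
    CalibrationError,
    GatingState,
    KineticScheme,
    calibrate_rates_to_targets,
    list_profiles,
    load_profile,
    scale_opening_rates,
    stationary_distribution,
)
from patchkin.profiles import open_probability

SO = (GatingState("shut"), GatingState("open", -1.5))


def two_state(k_so, k_os):
    return KineticScheme(SO, np.array([[0.0, k_so], [k_os, 0.0]]))


class TestStationaryDistribution:
    def test_symmetric_two_state_is_half_half(self):
        pi = stationary_distribution(two_state(1.0, 1.0))
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_two_state_matches_alpha_over_alpha_plus_beta(self):
        # analytic pi_open = k_so / (k_so + k_os)
        pi = stationary_distribution(two_state(11.11, 100.0))
        assert pi[1] == pytest.approx(11.11 / 111.11, abs=1e-9)
        assert pi[1] == pytest.approx(0.1, abs=1e-4)

    def test_symmetric_three_state_chain_is_uniform(self):
        states = (GatingState("shut"), GatingState("sub", -0.75), GatingState("open", -1.5))
        Q = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        pi = stationary_distribution(KineticScheme(states, Q))
        np.testing.assert_allclose(pi, [1 / 3] * 3, atol=1e-12)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            stationary_distribution(KineticScheme(SO, np.zeros((2, 2))))

    def test_disconnected_graph_rejected(self):
        states = (GatingState("shut"), GatingState("sub", -0.75), GatingState("open", -1.5))
        Q = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="connected"):
            stationary_distribution(KineticScheme(states, Q))

    def test_negative_offdiagonal_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            KineticScheme(SO, np.array([[0.0, -1.0], [1.0, 0.0]]))


class TestCalibration:
    def test_two_state_po_and_open_lifetime(self):
        # Po = 0.1, open lifetime 10 ms -> closing 100/s, opening 11.11/s
        sch = calibrate_rates_to_targets(
            {"shut": 0.9, "open": 0.1}, {"shut": None, "open": 10.0}
        )
        i, j = sch.index("open"), sch.index("shut")
        assert sch.Q[i, j] == pytest.approx(100.0)
        assert sch.Q[j, i] == pytest.approx(100.0 / 9.0, rel=1e-9)  # 11.11/s

    def test_symmetric_targets_give_symmetric_rates(self):
        sch = calibrate_rates_to_targets(
            {"shut": 0.5, "open": 0.5}, {"shut": 10.0, "open": 10.0}
        )
        assert sch.Q[0, 1] == pytest.approx(sch.Q[1, 0])

    @pytest.mark.parametrize("profile_name", ["WT", "R1398W", "F2484L"])
    @pytest.mark.parametrize("condition", ["rest", "pressure"])
    def test_round_trip_on_packaged_profiles(self, profile_name, condition):
        prof = load_profile(profile_name)
        tgt = prof.conditions[condition]
        sch = prof.scheme(condition)
        pi = stationary_distribution(sch)
        want = np.array([tgt.occupancy[s.label] for s in sch.states])
        np.testing.assert_allclose(pi, want, atol=1e-9)
        lifes = sch.mean_lifetimes_ms()
        want_l = np.array([tgt.mean_lifetime_ms[s.label] for s in sch.states])
        np.testing.assert_allclose(lifes, want_l, rtol=1e-9)

    def test_infeasible_targets_name_the_violated_state(self):
        # shut flux far beyond what sub+open can exchange
        with pytest.raises(CalibrationError, match="shut"):
            calibrate_rates_to_targets(
                {"shut": 0.9, "sub": 0.05, "open": 0.05},
                {"shut": 1.0, "sub": 50.0, "open": 50.0},
            )

    def test_occupancies_must_sum_to_one(self):
        with pytest.raises(CalibrationError, match="sum"):
            calibrate_rates_to_targets({"shut": 0.5, "open": 0.6}, {"shut": 10, "open": 10})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        po=st.floats(0.02, 0.6),
        sub_frac=st.floats(0.1, 0.9),
        l_sub=st.floats(0.5, 5.0),
        l_open=st.floats(1.0, 20.0),
        slack=st.floats(1.05, 3.0),
    )
    def test_feasible_targets_round_trip_exactly(self, po, sub_frac, l_sub, l_open, slack):
        occ = {"shut": 1 - po, "sub": po * sub_frac, "open": po * (1 - sub_frac)}
        # pick a shut lifetime comfortably inside the flux-feasibility bound
        cap = occ["sub"] / l_sub + occ["open"] / l_open
        l_shut = slack * occ["shut"] / cap
        life = {"shut": l_shut, "sub": l_sub, "open": l_open}
        flux = {s: occ[s] / life[s] for s in occ}
        total = sum(flux.values())
        assume(all(f < 0.999 * (total - f) for f in flux.values()))  # strictly feasible
        sch = calibrate_rates_to_targets(occ, life)
        pi = stationary_distribution(sch)
        np.testing.assert_allclose(pi, [occ["shut"], occ["sub"], occ["open"]], atol=1e-9)
        np.testing.assert_allclose(sch.mean_lifetimes_ms(), [l_shut, l_sub, l_open], rtol=1e-9)


class TestPackagedProfiles:
    def test_all_profiles_stationary_laws_are_valid(self):
        # pi Q = 0, pi >= 0, sum pi = 1 for every packaged scheme
        for name in list_profiles():
            prof = load_profile(name)
            conds = ["rest", "pressure", "step"] + (
                ["yoda1"] if prof.yoda1_po_fold else []
            )
            for cond in conds:
                sch = prof.scheme(cond)
                pi = stationary_distribution(sch)
                assert np.all(pi >= 0)
                assert pi.sum() == pytest.approx(1.0, abs=1e-12)
                np.testing.assert_allclose(pi @ sch.Q, 0.0, atol=1e-9)

    def test_yoda1_condition_hits_the_calibrated_po_fold(self, wt):
        base = open_probability(wt.scheme("pressure"))
        assert open_probability(wt.scheme("yoda1")) / base == pytest.approx(
            wt.yoda1_po_fold, rel=1e-6
        )

    def test_yoda1_preserves_conductances(self, wt):
        # agonist modifies gating only: state currents unchanged
        for s_base, s_yoda in zip(wt.scheme("pressure").states, wt.scheme("yoda1").states):
            assert s_base.unitary_current_pA == s_yoda.unitary_current_pA

    def test_pressure_interpolation_is_monotone_for_wt(self, wt):
        pos = [open_probability(wt.scheme_for_pressure(p)) for p in (0, -10, -20, -30)]
        assert all(a < b for a, b in zip(pos, pos[1:]))

    def test_scale_opening_rates_requires_positive_factor(self, wt):
        with pytest.raises(ValueError):
            scale_opening_rates(wt.scheme("rest"), 0.0)
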