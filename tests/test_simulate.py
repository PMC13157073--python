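"""Gillespie path simulation, trace rendering and cohort generation."""
import numpy as np
import pytest
from scipy import stats as sps

from patchkin import (
    GatingState,
    IdealizedPath,
    KineticScheme,
    SimConfig,
    StimulusProtocol,
    make_cohort,
    render_trace,
    simulate_path,
    simulate_recording,
)
from patchkin.simulate import _segment_scheme


def _patched_profile(wt, scheme):
    """WT profile whose every pressure condition maps onto one fixed scheme."""
    import copy

    prof = copy.copy(wt)
    prof._schemes = {}
    prof.scheme_for_pressure = lambda p, yoda1=False: scheme
    return prof


@pytest.fixture
def symmetric_profile(wt):
    sch = KineticScheme(
        (GatingState("shut"), GatingState("open", -1.5)),
        np.array([[0.0, 100.0], [100.0, 0.0]]),
    )
    return _patched_profile(wt, sch)


class TestSimulatePath:
    def test_frozen_scheme_gives_single_full_length_dwell(self, wt):
        sch = KineticScheme((GatingState("shut"), GatingState("open", -1.5)), np.zeros((2, 2)))
        path = simulate_path(_patched_profile(wt, sch), StimulusProtocol.constant(0, 500), seed=3)
        assert len(path) == 1
        assert path.duration_ms[0] == pytest.approx(500.0)
        assert path.states[0] == "shut"

    def test_dwells_tile_the_requested_duration(self, wt):
        path = simulate_path(wt, StimulusProtocol.constant(-30, 2000), seed=11)
        assert path.start_ms[0] == 0.0
        assert path.total_ms == pytest.approx(2000.0)
        np.testing.assert_allclose(
            path.start_ms[1:], (path.start_ms + path.duration_ms)[:-1], atol=1e-9
        )

    def test_symmetric_two_state_occupancy_near_half(self, symmetric_profile):
        path = simulate_path(symmetric_profile, StimulusProtocol.constant(0, 100_000), seed=5)
        open_frac = path.duration_ms[path.states == "open"].sum() / path.total_ms
        n = (path.states == "open").sum()
        se = 0.5 / np.sqrt(n)  # binomial-ish SE from dwell counts
        assert abs(open_frac - 0.5) < 3 * se

    def test_mean_open_dwell_matches_exit_rate(self, symmetric_profile):
        # closing rate 100/s -> mean open dwell 10 ms
        path = simulate_path(symmetric_profile, StimulusProtocol.constant(0, 200_000), seed=9)
        d = path.dwells("open")
        assert d.size > 1000
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - 10.0) < 3 * se

    def test_dwell_distributions_are_exponential(self, symmetric_profile):
        # KS at alpha = 0.01 should pass for >= 95% of seeds
        fails = 0
        n_seeds = 40
        for seed in range(n_seeds):
            path = simulate_path(symmetric_profile, StimulusProtocol.constant(0, 30_000), seed=seed)
            d = path.dwells("open")
            p = sps.kstest(d, "expon", args=(0, 10.0)).pvalue
            fails += p < 0.01
        assert fails <= int(0.05 * n_seeds) + 1

    def test_identical_seed_gives_identical_path(self, wt):
        proto = StimulusProtocol.constant(-30, 5000)
        a = simulate_path(wt, proto, seed=42)
        b = simulate_path(wt, proto, seed=42)
        np.testing.assert_array_equal(a.start_ms, b.start_ms)
        assert list(a.states) == list(b.states)

    def test_state_carries_over_pressure_step_boundary(self, wt):
        proto = StimulusProtocol.step(500, 500, -30)
        path = simulate_path(wt, proto, seed=1)
        # contiguity across the boundary and no zero-length dwell at 500 ms
        assert np.all(path.duration_ms > 0)
        assert path.total_ms == pytest.approx(1000.0)

    def test_inactivation_only_during_pressure(self, wt):
        rest = _segment_scheme(wt, 0.0, False, True)
        step = _segment_scheme(wt, -30.0, False, True)
        i_rest = rest.index("inactivated")
        assert rest.Q[rest.index("open"), i_rest] == 0.0  # no entry at rest
        assert step.Q[step.index("open"), step.index("inactivated")] == pytest.approx(
            1000.0 / wt.tau_inact_ms
        )
        assert step.Q[step.index("inactivated"), step.index("shut")] == 0.0  # absorbing in step


class TestRenderTrace:
    def _flat_path(self, state, level, duration=1000.0):
        return IdealizedPath(
            states=np.array([state], dtype=object),
            start_ms=np.array([0.0]),
            duration_ms=np.array([duration]),
            level_pA=np.array([level]),
        )

    def test_always_shut_no_noise_is_zero(self, wt):
        cfg = SimConfig(duration_ms=1000, noise_sd_pA=0.0, seed=1)
        tr = render_trace([self._flat_path("shut", 0.0)], wt, cfg)
        np.testing.assert_allclose(tr.current_pA, 0.0, atol=1e-12)

    def test_always_open_no_noise_settles_at_unitary(self, wt):
        cfg = SimConfig(duration_ms=1000, noise_sd_pA=0.0, seed=1)
        tr = render_trace([self._flat_path("open", -1.5)], wt, cfg)
        burn = int(tr.burn_in_ms / tr.dt_ms)
        np.testing.assert_allclose(tr.current_pA[burn:], -1.5, atol=1e-3)

    def test_two_open_channels_sum_to_double(self, wt):
        cfg = SimConfig(duration_ms=1000, noise_sd_pA=0.0, seed=1, n_channels=2)
        tr = render_trace([self._flat_path("open", -1.5)] * 2, wt, cfg)
        burn = int(tr.burn_in_ms / tr.dt_ms)
        np.testing.assert_allclose(tr.current_pA[burn:], -3.0, atol=2e-3)

    def test_mismatched_durations_rejected(self, wt):
        cfg = SimConfig(duration_ms=1000, seed=1)
        with pytest.raises(ValueError, match="mismatched"):
            render_trace(
                [self._flat_path("open", -1.5, 1000.0), self._flat_path("open", -1.5, 900.0)],
                wt,
                cfg,
            )

    def test_noise_sd_change_leaves_underlying_path_unchanged(self, wt):
        proto = StimulusProtocol.constant(-30, 2000)
        _, paths_a = simulate_recording(wt, proto, SimConfig(duration_ms=2000, seed=3, noise_sd_pA=0.15))
        _, paths_b = simulate_recording(wt, proto, SimConfig(duration_ms=2000, seed=3, noise_sd_pA=0.5))
        np.testing.assert_array_equal(paths_a[0].start_ms, paths_b[0].start_ms)
        assert list(paths_a[0].states) == list(paths_b[0].states)


class TestMakeCohort:
    def test_single_cell_equals_direct_simulation(self, wt):
        proto = StimulusProtocol.constant(-30, 1000)
        cfg = SimConfig(duration_ms=1000, seed=0)
        (tr,) = make_cohort(wt, proto, cfg, 1, base_seed=21)
        direct, _ = simulate_recording(wt, proto, SimConfig(duration_ms=1000, seed=21))
        np.testing.assert_array_equal(tr.current_pA, direct.current_pA)

    def test_same_base_seed_is_bitwise_reproducible(self, wt):
        proto = StimulusProtocol.constant(-30, 1000)
        cfg = SimConfig(duration_ms=1000)
        a = make_cohort(wt, proto, cfg, 3, base_seed=5)
        b = make_cohort(wt, proto, cfg, 3, base_seed=5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.current_pA, tb.current_pA)

    def test_disjoint_seed_ranges_give_distinct_traces(self, wt):
        proto = StimulusProtocol.constant(-30, 1000)
        cfg = SimConfig(duration_ms=1000)
        a = make_cohort(wt, proto, cfg, 2, base_seed=100)
        b = make_cohort(wt, proto, cfg, 2, base_seed=200)
        for ta in a:
            for tb in b:
                assert not np.array_equal(ta.current_pA, tb.current_pA)


class TestProtocolValidation:
    def test_segments_must_be_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            StimulusProtocol(-60.0, ((0.0, 100.0, 0.0), (150.0, 200.0, -30.0)))

    def test_sampling_must_beat_nyquist(self):
        with pytest.raises(ValueError, match="twice"):
            SimConfig(sampling_rate_hz=3000.0, acq_filter_hz=2000.0, duration_ms=10)
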