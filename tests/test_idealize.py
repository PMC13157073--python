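"""Amplitude histograms, mixture fits, channel counting, Viterbi, dead time."""
import numpy as np
import pytest

from patchkin import (
    AmplitudeModel,
    allpoint_histogram,
    estimate_channel_count,
    fit_amplitude_model,
    impose_dead_time,
    viterbi_idealize,
)
from patchkin.idealize import AmplitudeComponent, _viterbi_kernel
from patchkin.path import IdealizedPath
from conftest import make_trace


class TestAllpointHistogram:
    def test_identical_samples_fill_one_bin(self):
        h = allpoint_histogram(np.full(1000, -1.5), 0.02)
        assert (h.counts > 0).sum() == 1
        assert h.counts.max() == 1000

    def test_two_exact_levels_fill_two_bins(self):
        x = np.tile([0.0 + 0.01, -1.5 + 0.01], 500)  # mid-bin values
        h = allpoint_histogram(x, 0.02)
        assert (h.counts > 0).sum() == 2
        assert h.n_samples == 1000

    def test_moments_are_conserved(self):
        rng = np.random.default_rng(0)
        x = rng.normal(-0.5, 0.3, 100_000)
        h = allpoint_histogram(x, 0.02)
        hist_mean = np.average(h.centers, weights=h.counts)
        se = 0.3 / np.sqrt(x.size)
        assert abs(hist_mean - x.mean()) < 3 * se + 0.02

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            allpoint_histogram(np.array([]))


class TestAmplitudeMixture:
    def test_two_gaussian_generative_recovery(self):
        rng = np.random.default_rng(1)
        n = 200_000
        member = rng.random(n) < 0.1
        x = np.where(member, rng.normal(-1.5, 0.2, n), rng.normal(0.0, 0.2, n))
        model = fit_amplitude_model(x, n_components=2)
        assert model.shut.mean_pA == pytest.approx(0.0, abs=0.02)
        assert model.conducting[-1].mean_pA == pytest.approx(-1.5, abs=0.02)
        assert model.shut.area == pytest.approx(0.9, abs=0.01)
        assert model.conducting[-1].area == pytest.approx(0.1, abs=0.01)

    def test_single_population_flags_degenerate_second_component(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 0.15, 100_000)
        model = fit_amplitude_model(x, n_components=2)
        real = [c for c in model.components if not c.degenerate]
        assert sum(c.area for c in real) >= 0.99

    def test_noiseless_two_level_trace_recovers_exact_fractions(self):
        x = np.concatenate([np.zeros(7500), np.full(2500, -1.5)])
        rng = np.random.default_rng(3)
        x = x + rng.normal(0, 0.01, x.size)  # sharpen peaks but keep them fittable
        model = fit_amplitude_model(x, n_components=2, bin_width_pA=0.005)
        assert model.shut.area == pytest.approx(0.75, abs=0.01)
        assert model.conducting[-1].area == pytest.approx(0.25, abs=0.01)

    def test_areas_are_normalized_and_ordered(self, wt_recording):
        trace, _ = wt_recording
        model = fit_amplitude_model(trace, n_components=3)
        assert sum(c.area for c in model.components) == pytest.approx(1.0)
        means = np.abs(model.means())
        assert np.all(np.diff(means) >= 0)


def model_from_means(means, area_open=0.1):
    comps = [AmplitudeComponent(0.0, 0.1, 1 - area_open * (len(means) - 1))]
    comps += [AmplitudeComponent(m, 0.1, area_open) for m in means[1:]]
    return AmplitudeModel(comps)


class TestChannelCount:
    def test_single_open_peak_gives_one(self):
        n, flag = estimate_channel_count(model_from_means([0.0, -1.5]), -1.5)
        assert (n, flag) == (1, False)

    def test_stacked_peak_gives_two(self):
        n, _ = estimate_channel_count(model_from_means([0.0, -1.5, -3.0]), -1.5)
        assert n == 2

    def test_sub_level_is_not_a_channel(self):
        n, _ = estimate_channel_count(model_from_means([0.0, -0.75, -1.5]), -1.5)
        assert n == 1

    def test_shut_only_patch_reports_one_with_flag(self):
        model = AmplitudeModel([AmplitudeComponent(0.0, 0.1, 1.0)])
        n, flag = estimate_channel_count(model, -1.5)
        assert (n, flag) == (1, True)


def brute_force_viterbi(obs, levels, noise_sd, log_trans):
    """Exhaustive maximum-probability path over all K^T state sequences."""
    from itertools import product

    K = len(levels)
    best, best_seq = -np.inf, None
    for seq in product(range(K), repeat=len(obs)):
        lp = 0.0
        for t, k in enumerate(seq):
            lp += -((obs[t] - levels[k]) ** 2) / (2 * noise_sd**2)
            if t:
                lp += log_trans[seq[t - 1], k]
        if lp > best:
            best, best_seq = lp, seq
    return np.array(best_seq)


class TestViterbi:
    def test_noiseless_three_level_trace_recovered_exactly(self):
        levels = {"shut": 0.0, "sub": -0.75, "open": -1.5}
        seq = np.array(["shut"] * 20 + ["sub"] * 15 + ["open"] * 25 + ["shut"] * 20)
        x = np.array([levels[s] for s in seq])
        tr = make_trace(x)
        path = viterbi_idealize(tr, levels, noise_sd_pA=0.05, stay_prob=0.95)
        decoded = path.states_at(tr.time_ms + tr.dt_ms / 2)
        assert list(decoded) == list(seq)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        levels = np.array([0.0, -0.75, -1.5])
        log_trans = np.log(np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]]))
        for _ in range(20):
            truth = rng.integers(0, 3, size=8)
            obs = levels[truth] + rng.normal(0, 0.4, 8)
            kern = _viterbi_kernel(obs, levels, 0.4, log_trans)
            brute = brute_force_viterbi(obs, levels, 0.4, log_trans)
            np.testing.assert_array_equal(kern, brute)

    def test_matches_hmmlearn_decoder(self):
        # independent cross-check against an established HMM implementation
        from hmmlearn.hmm import GaussianHMM

        rng = np.random.default_rng(4)
        levels = np.array([0.0, -0.75, -1.5])
        stay = 0.98
        trans = np.full((3, 3), (1 - stay) / 2)
        np.fill_diagonal(trans, stay)
        truth = np.repeat(rng.integers(0, 3, 60), rng.integers(5, 50, 60))
        obs = levels[truth] + rng.normal(0, 0.15, truth.size)

        hmm = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        hmm.startprob_ = np.full(3, 1 / 3)
        hmm.transmat_ = trans
        hmm.means_ = levels.reshape(-1, 1)
        hmm.covars_ = np.full((3, 1), 0.15**2)
        _, ref = hmm.decode(obs.reshape(-1, 1), algorithm="viterbi")

        tr = make_trace(obs)
        path = viterbi_idealize(
            tr, {"shut": 0.0, "sub": -0.75, "open": -1.5}, 0.15, stay_prob=stay
        )
        mine = path.states_at(tr.time_ms + tr.dt_ms / 2)
        label = np.array(["shut", "sub", "open"], dtype=object)
        np.testing.assert_array_equal(mine, label[ref])

    def test_overwhelming_noise_with_sticky_prior_gives_single_dwell(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 5.0, 2000)  # noise >> level spacing
        tr = make_trace(x)
        path = viterbi_idealize(tr, {"shut": 0.0, "open": -1.5}, 5.0, stay_prob=0.9999)
        assert len(path) == 1

    def test_non_finite_samples_rejected(self):
        tr = make_trace(np.array([0.0, np.nan, 0.0]))
        with pytest.raises(ValueError, match="non-finite"):
            viterbi_idealize(tr, {"shut": 0.0, "open": -1.5}, 0.1)


def path_from(durs, states, levels=None):
    durs = np.asarray(durs, float)
    levels = levels or {"shut": 0.0, "sub": -0.75, "open": -1.5}
    return IdealizedPath(
        states=np.array(states, dtype=object),
        start_ms=np.concatenate(([0.0], np.cumsum(durs[:-1]))),
        duration_ms=durs,
        level_pA=np.array([levels[s] for s in states]),
    )


class TestDeadTime:
    def test_all_long_dwells_unchanged(self):
        p = path_from([10, 20, 10], ["shut", "open", "shut"])
        out = impose_dead_time(p, 0.5)
        np.testing.assert_array_equal(out.duration_ms, p.duration_ms)

    def test_brief_opening_absorbed_into_shut(self):
        p = path_from([10, 0.1, 10], ["shut", "open", "shut"])
        out = impose_dead_time(p, 0.5)
        assert len(out) == 1
        assert out.states[0] == "shut"
        assert out.duration_ms[0] == pytest.approx(20.1)

    def test_zero_dead_time_is_identity(self):
        p = path_from([10, 0.1, 10], ["shut", "open", "shut"])
        out = impose_dead_time(p, 0.0)
        assert out is p

    def test_total_duration_conserved_and_events_monotone(self):
        rng = np.random.default_rng(6)
        durs = rng.exponential(1.0, 200)
        states = [("shut", "open")[i % 2] for i in range(200)]
        p = path_from(durs, states)
        prev = len(p)
        for dead in (0.1, 0.3, 0.8, 2.0):
            out = impose_dead_time(p, dead)
            assert out.duration_ms.sum() == pytest.approx(p.duration_ms.sum())
            assert len(out) <= prev
            prev = len(out)
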