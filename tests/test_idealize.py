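"""HMM idealization, dwell-time extraction and rate estimation.

The Viterbi decoder is checked against an exhaustive path enumeration on
short traces; rate recovery is checked against the generating rates of
synthetic data.
"""

from dataclasses import replace
from itertools import product

import numpy as np
import pytest
from scipy import stats

from smfretkit.errors import EmptyInputError
from smfretkit.idealize import (
    DwellSet,
    estimate_rates,
    extract_dwells,
    fit_dwell_distribution,
    fit_hmm,
    state_occupancy,
    viterbi_paths,
)
from smfretkit.traces import FretTrace, analyze_trace

from conftest import make_traces


def _fret_trace(e, frame_dt=0.1):
    e = np.asarray(e, dtype=float)
    return FretTrace(efficiency=e, donor=1 - e, acceptor=e, frame_dt=frame_dt)


def brute_force_viterbi(model, obs):
    """Exhaustive max-likelihood path over all 2^L state sequences."""
    means, sds = model.emission_means, model.emission_sds
    log_start = np.log(model.start_prob)
    log_trans = np.log(model.transition_matrix)
    log_emit = np.array(
        [stats.norm.logpdf(obs, means[s], sds[s]) for s in range(2)]
    )  # (2, L)
    best_lp, best_path = -np.inf, None
    for path in product(range(2), repeat=len(obs)):
        lp = log_start[path[0]] + log_emit[path[0], 0]
        for t in range(1, len(obs)):
            lp += log_trans[path[t - 1], path[t]] + log_emit[path[t], t]
        if lp > best_lp:
            best_lp, best_path = lp, np.asarray(path)
    return best_path, best_lp


class TestFitHmm:
    def test_recovers_emission_means(self, nobleach_canonical):
        sc = replace(nobleach_canonical, n_frames=400)
        trs = make_traces(sc, 0.4, 0.22, 120, seed=31)
        fts = [analyze_trace(t) for t in trs]
        model, paths = fit_hmm(fts, seed=1)
        assert model.emission_means[0] == pytest.approx(0.32, abs=0.02)
        assert model.emission_means[1] == pytest.approx(0.57, abs=0.02)
        assert not model.degenerate

    def test_transition_rows_sum_to_one(self, nobleach_canonical):
        sc = replace(nobleach_canonical, n_frames=200)
        trs = make_traces(sc, 0.4, 0.22, 30, seed=32)
        model, _ = fit_hmm([analyze_trace(t) for t in trs], seed=2)
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_single_state_data_flagged_degenerate(self, nobleach_canonical):
        sc = replace(nobleach_canonical, n_frames=300)
        trs = make_traces(sc, 0.0, 0.2, 40, seed=33)  # never leaves state 0
        model, paths = fit_hmm([analyze_trace(t) for t in trs], seed=3)
        assert model.degenerate
        # either one state is starved or the two means collapsed within 1 sd
        occ = state_occupancy(paths, 1)
        collapsed = (
            model.emission_means[1] - model.emission_means[0]
            < max(model.emission_sds)
        )
        assert occ < 0.02 or occ > 0.98 or collapsed

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            fit_hmm([], seed=0)

    def test_viterbi_matches_exhaustive_enumeration(self, nobleach_canonical):
        # train once on realistic data, then decode short segments both ways
        sc = replace(nobleach_canonical, n_frames=200)
        trs = make_traces(sc, 0.5, 0.4, 25, seed=34)
        fts = [analyze_trace(t) for t in trs]
        model, _ = fit_hmm(fts, seed=4)
        from smfretkit.pipeline import _as_hmmlearn

        gm = _as_hmmlearn(model)
        rng = np.random.default_rng(5)
        for ft in fts[:12]:
            e = ft.prebleach_efficiency()
            start = int(rng.integers(0, e.size - 12))
            seg = e[start : start + 12]
            decoded = viterbi_paths(gm, [seg])[0]
            brute_path, brute_lp = brute_force_viterbi(model, seg)
            # the decoded path must attain the global maximum likelihood
            lp_decoded = _path_loglik(model, seg, decoded)
            assert lp_decoded == pytest.approx(brute_lp, abs=1e-8)

    def test_occupancy_matches_rate_ratio(self, nobleach_canonical):
        sc = replace(nobleach_canonical, n_frames=600)
        trs = make_traces(sc, 0.3, 0.3, 60, seed=35)
        fts = [analyze_trace(t) for t in trs]
        model, paths = fit_hmm(fts, seed=6)
        occ = state_occupancy(paths, 1)
        assert occ == pytest.approx(0.5, abs=0.03)


def _path_loglik(model, obs, path):
    lp = np.log(model.start_prob[path[0]]) + stats.norm.logpdf(
        obs[0], model.emission_means[path[0]], model.emission_sds[path[0]]
    )
    for t in range(1, len(obs)):
        lp += np.log(model.transition_matrix[path[t - 1], path[t]])
        lp += stats.norm.logpdf(
            obs[t], model.emission_means[path[t]], model.emission_sds[path[t]]
        )
    return lp


class TestDwells:
    def test_run_length_example(self):
        # path 0 0 0 1 1 1 1 0 0 at dt = 0.1: low dwells 0.3*, 0.2* (censored),
        # high dwell 0.4 (interior)
        ds = extract_dwells([np.array([0, 0, 0, 1, 1, 1, 1, 0, 0])], frame_dt=0.1)
        assert ds.durations == pytest.approx([0.3, 0.4, 0.2])
        assert list(ds.censored) == [True, False, True]
        assert ds.dwells_high == pytest.approx([0.4])
        assert ds.dwells_low.size == 0

    def test_constant_path_fully_censored(self):
        ds = extract_dwells([np.zeros(50, dtype=int)], frame_dt=0.1)
        assert ds.durations.size == 1
        assert ds.censored.all()
        assert ds.dwells_low.size == 0

    def test_empirical_dwell_rate_recovery(self):
        # geometric dwells at k = 0.2 /s in a 200 s window; the raw interior
        # mean is short-biased by the window, the censored-ML fit is not
        rng = np.random.default_rng(7)
        paths = []
        p_exit = 1 - np.exp(-0.2 * 0.1)
        for _ in range(300):
            s, path = 0, []
            for _ in range(2000):
                path.append(s)
                if rng.random() < p_exit:
                    s = 1 - s
            paths.append(np.asarray(path))
        ds = extract_dwells(paths, frame_dt=0.1)
        d = np.concatenate([ds.dwells_low, ds.dwells_high])
        assert d.size > 10_000
        # interior dwell mean ~ dt/p_exit = 5 s (windowing bias is negligible
        # here because the window is 40x the mean dwell)
        assert d.mean() == pytest.approx(0.1 / p_exit, rel=0.02)
        # the censored-aware ML estimate recovers the generating rate
        rates = estimate_rates(ds, n_boot=0)
        assert rates.k_dock == pytest.approx(0.2, rel=0.05)
        assert rates.k_undock == pytest.approx(0.2, rel=0.05)


class TestDwellFit:
    def test_pure_exponential_recovered(self):
        rng = np.random.default_rng(8)
        d = rng.exponential(2.0, size=5000)  # k = 0.5
        d = np.round(d / 0.1) * 0.1  # frame quantization
        fit = fit_dwell_distribution(d, n_components=2, frame_dt=0.1)
        assert fit.dominant_rate == pytest.approx(0.5, rel=0.05)

    def test_two_component_mixture_recovered(self):
        rng = np.random.default_rng(9)
        d = np.concatenate(
            [rng.exponential(10.0, 5000), rng.exponential(1.0, 5000)]
        )  # k = 0.1 and 1.0
        fit = fit_dwell_distribution(d, n_components=2, frame_dt=0.1)
        assert fit.n_components == 2
        assert sorted(fit.rates) == pytest.approx([0.1, 1.0], rel=0.15)

    def test_small_sample_flagged_with_mean_rate(self):
        d = np.full(20, 4.0)
        fit = fit_dwell_distribution(d, frame_dt=0.1)
        assert "insufficient-data" in fit.flags
        assert fit.dominant_rate == pytest.approx(1 / 3.8, rel=1e-6)

    def test_degenerate_equal_dwells_flagged(self):
        fit = fit_dwell_distribution(np.full(100, 4.0), frame_dt=0.1)
        assert "insufficient-variance" in fit.flags


class TestRates:
    def test_scale_equivariance(self):
        rng = np.random.default_rng(10)
        durs = rng.exponential(2.0, 400)
        ds = DwellSet(
            durations=durs,
            states=rng.integers(0, 2, 400),
            censored=np.zeros(400, dtype=bool),
            trace_ids=np.repeat(np.arange(40), 10),
            frame_dt=0.1,
        )
        ds2 = DwellSet(
            durations=2 * durs, states=ds.states, censored=ds.censored,
            trace_ids=ds.trace_ids, frame_dt=0.2,
        )
        r1 = estimate_rates(ds, n_boot=0)
        r2 = estimate_rates(ds2, n_boot=0)
        assert r2.k_dock == pytest.approx(r1.k_dock / 2, rel=1e-6)
        assert r2.k_undock == pytest.approx(r1.k_undock / 2, rel=1e-6)

    def test_detailed_balance_occupancy(self, nobleach_canonical):
        # k_dock = k_undock: Viterbi occupancy 0.5 and rates within each
        # other's bootstrap CI
        sc = replace(nobleach_canonical, n_frames=500)
        trs = make_traces(sc, 0.25, 0.25, 80, seed=36)
        fts = [analyze_trace(t) for t in trs]
        model, paths = fit_hmm(fts, seed=11)
        ds = extract_dwells(paths, model.frame_dt)
        rates = estimate_rates(ds, seed=12)
        assert state_occupancy(paths, 1) == pytest.approx(0.5, abs=0.04)
        lo, hi = rates.ci_dock
        assert lo <= rates.k_undock * 1.15 and hi >= rates.k_undock * 0.85

    def test_rate_grid_recovery(self, nobleach_canonical):
        # median relative error < 10% over a rate grid (dwells >= 5 frames)
        errors = []
        for k in (0.05, 0.1, 0.2, 0.5, 1.0):
            trs = make_traces(nobleach_canonical, k, k, 60, seed=37)
            fts = [analyze_trace(t) for t in trs]
            model, paths = fit_hmm(fts, seed=13)
            ds = extract_dwells(paths, model.frame_dt)
            rates = estimate_rates(ds, n_boot=0, seed=14)
            errors.append(abs(rates.k_dock - k) / k)
            errors.append(abs(rates.k_undock - k) / k)
        assert np.median(errors) < 0.10
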