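"""Generator correctness: Markov paths, Hill rates, trace and movie rendering."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfretkit.errors import InvalidParameterError
from smfretkit.synth import (
    KineticScenario,
    MovieSpec,
    make_titration_dataset,
    mg_dependent_dock_rate,
    render_movie,
    render_trace,
    sample_state_path,
    stationary_docked_fraction,
)


class TestStatePath:
    def test_absorbing_when_exit_rate_zero(self):
        path = sample_state_path(0.0, 0.2, 100.0, seed=1, start=0)
        assert path.n_transitions == 0
        assert path.occupancy(0) == 1.0

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            sample_state_path(-0.1, 0.2, 10.0, seed=0)
        with pytest.raises(InvalidParameterError):
            sample_state_path(0.1, 0.2, 0.0, seed=0)

    def test_symmetric_rates_give_half_occupancy(self):
        occ = np.mean([sample_state_path(0.5, 0.5, 1e4, seed=s).occupancy(1) for s in range(20)])
        assert occ == pytest.approx(0.5, abs=0.02)

    def test_stationary_occupancy_matches_rate_ratio(self):
        # 100 independent paths; compare to k01/(k01+k10) within 3 Monte Carlo s.e.
        k01, k10 = 0.3, 0.1
        occs = [sample_state_path(k01, k10, 1e4, seed=s).occupancy(1) for s in range(100)]
        se = np.std(occs, ddof=1) / 10
        assert abs(np.mean(occs) - 0.75) < 3 * se

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        k01=st.floats(0.05, 1.0),
        k10=st.floats(0.05, 1.0),
    )
    def test_stationary_occupancy_property(self, k01, k10):
        occs = [sample_state_path(k01, k10, 3e3, seed=s).occupancy(1) for s in range(40)]
        se = max(np.std(occs, ddof=1) / np.sqrt(40), 1e-4)
        assert abs(np.mean(occs) - k01 / (k01 + k10)) < 4 * se

    def test_dwell_mean_is_inverse_exit_rate(self):
        # pool > 1000 interior dwells of state 0 at exit rate 0.5
        dwells = []
        for s in range(80):
            p = sample_state_path(0.5, 0.5, 500.0, seed=s)
            edges = np.concatenate(([0.0], p.transition_times, [p.duration]))
            seg = np.diff(edges)
            interior = seg[1:-1]
            states = p.states[1:-1]
            dwells.extend(interior[states == 0])
        dwells = np.asarray(dwells)
        assert dwells.size > 1000
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 2.0) < 3 * se

    def test_fixed_seed_reproducible(self):
        a = sample_state_path(0.3, 0.2, 100.0, seed=42)
        b = sample_state_path(0.3, 0.2, 100.0, seed=42)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.transition_times, b.transition_times)


class TestDockRate:
    def test_midpoint_is_half_maximal(self, canonical):
        assert mg_dependent_dock_rate(canonical.mg_half, canonical) == pytest.approx(
            canonical.k_dock_max / 2
        )

    def test_zero_mg_gives_zero_rate(self, canonical):
        assert mg_dependent_dock_rate(0.0, canonical) == 0.0

    def test_printed_midpoint_value(self):
        sc = KineticScenario(k_dock_max=1.0, mg_half=3.9, hill_n=2.0)
        assert mg_dependent_dock_rate(3.9, sc) == pytest.approx(0.5)

    def test_monotone_in_mg(self, canonical):
        mg = np.linspace(0, 50, 200)
        k = [mg_dependent_dock_rate(m, canonical) for m in mg]
        assert np.all(np.diff(k) >= 0)


class TestRenderTrace:
    def test_noiseless_total_is_conserved(self, noiseless_canonical):
        path = sample_state_path(0.4, 0.22, noiseless_canonical.duration, seed=3)
        tr = render_trace(path, noiseless_canonical, seed=4)
        assert np.allclose(tr.total, noiseless_canonical.total_intensity)

    def test_equal_split_at_half_efficiency(self, noiseless_canonical):
        sc = replace(noiseless_canonical, fret_means=(0.5, 0.9))
        path = sample_state_path(0.0, 0.2, sc.duration, seed=1, start=0)
        tr = render_trace(path, sc, seed=2)
        assert np.allclose(tr.donor, tr.acceptor)

    def test_noiseless_efficiency_equals_state_means(self, noiseless_canonical):
        path = sample_state_path(0.3, 0.3, noiseless_canonical.duration, seed=7)
        tr = render_trace(path, noiseless_canonical, seed=8)
        e = tr.acceptor / tr.total
        means = np.asarray(noiseless_canonical.fret_means)
        frames = path.frame_states(noiseless_canonical.frame_dt, noiseless_canonical.n_frames)
        # frames without a transition inside them match the state mean exactly
        pure = np.isin(np.round(e, 12), np.round(means, 12))
        assert pure.mean() > 0.9
        assert np.allclose(e[pure], means[frames[pure]])

    def test_short_path_rejected(self, noiseless_canonical):
        path = sample_state_path(0.3, 0.3, 10.0, seed=0)
        with pytest.raises(InvalidParameterError):
            render_trace(path, noiseless_canonical, seed=0)

    def test_mean_donor_bleach_frame(self, canonical):
        # bleach clock 0.05 s^-1 at 0.1 s/frame -> mean frame 1/(0.05*0.1) = 200
        sc = replace(canonical, bleach_rate_donor=0.05, bleach_rate_acceptor=0.0,
                     n_frames=10_000)
        frames = []
        rng = np.random.default_rng(12)
        path = sample_state_path(0.0, 0.2, sc.duration, seed=1, start=0)
        for _ in range(4000):
            tr = render_trace(path, sc, rng)
            bf = tr.meta["true_bleach_donor"]
            frames.append(sc.n_frames if bf is None else bf)
        frames = np.asarray(frames, dtype=float)
        se = frames.std(ddof=1) / np.sqrt(frames.size)
        assert abs(frames.mean() - 200.0) < 3 * se + 1.0  # +1 for floor discretization

    def test_acceptor_bleach_moves_intensity_to_donor(self, canonical):
        sc = replace(canonical, bleach_rate_donor=0.0, bleach_rate_acceptor=5.0,
                     shot_noise=False, read_noise_sd=0.0, fret_sds=(0.0, 0.0))
        path = sample_state_path(0.0, 0.2, sc.duration, seed=1, start=1)
        tr = render_trace(path, sc, seed=6)
        bf = tr.meta["true_bleach_acceptor"]
        assert bf is not None and bf < 100
        post = slice(bf, None)
        assert np.allclose(tr.total[post], sc.total_intensity)
        assert np.allclose(tr.acceptor[post] / tr.total[post], sc.donor_only_fret)


class TestRenderMovie:
    def _flat_traces(self, scenario, value, n, n_frames):
        from smfretkit.core import IntensityTrace

        return [
            IntensityTrace(np.full(n_frames, value), np.full(n_frames, value))
            for _ in range(n)
        ]

    def test_zero_intensity_zero_noise_is_flat_background(self):
        spec = MovieSpec(frame_shape=(40, 80), n_molecules=2, background_level=7.0,
                         read_noise_sd=0.0, gain=0.0, seed=0)
        traces = self._flat_traces(None, 0.0, 2, 10)
        mov = render_movie(spec, traces, [(15, 15), (15, 25)])
        assert np.allclose(mov.stack, 7.0)

    def test_noiseless_flux_conservation(self):
        spec = MovieSpec(frame_shape=(40, 80), n_molecules=1, background_level=5.0,
                         read_noise_sd=0.0, gain=0.0, seed=0)
        traces = self._flat_traces(None, 500.0, 1, 6)
        mov = render_movie(spec, traces, [(20, 20)])
        flux = mov.stack.sum(axis=(1, 2)) - 5.0 * 40 * 80
        # donor + acceptor spots both carry the trace value
        assert np.allclose(flux, 2 * 500.0, rtol=1e-3)

    def test_poisson_variance_matches_mean(self):
        spec = MovieSpec(frame_shape=(40, 80), n_molecules=1, background_level=0.0,
                         read_noise_sd=0.0, gain=1.0, seed=3)
        traces = self._flat_traces(None, 1000.0, 1, 800)
        mov = render_movie(spec, traces, [(20, 20)])
        integrated = mov.stack.sum(axis=(1, 2))  # Poisson with mean 2000 per frame
        mean, var = integrated.mean(), integrated.var(ddof=1)
        assert abs(var - mean) < 5 * mean * np.sqrt(2 / 799)

    def test_overlap_warning(self):
        spec = MovieSpec(frame_shape=(40, 80), n_molecules=2, psf_sigma=1.5, seed=0)
        traces = self._flat_traces(None, 100.0, 2, 4)
        mov = render_movie(spec, traces, [(15, 15), (17, 15)])
        assert any("overlapping" in w for w in mov.warnings)

    def test_seed_determinism(self):
        spec = MovieSpec(frame_shape=(40, 80), n_molecules=1, seed=11)
        traces = self._flat_traces(None, 300.0, 1, 5)
        a = render_movie(spec, traces, [(20, 20)]).stack
        b = render_movie(spec, traces, [(20, 20)]).stack
        assert np.array_equal(a, b)


class TestTitrationDataset:
    def test_empty_levels_rejected(self, canonical):
        with pytest.raises(InvalidParameterError):
            make_titration_dataset(canonical, "mg", [], 10, seed=0)

    def test_trna_isotherm_midpoint(self, canonical):
        assert stationary_docked_fraction(canonical.K_d, canonical, "tRNA") == pytest.approx(0.5)

    def test_trna_saturation_value(self, canonical):
        # 2000 nM at K_d = 40 nM -> 2000/2040
        f = stationary_docked_fraction(2000.0, canonical, "tRNA")
        assert f == pytest.approx(2000 / 2040, abs=1e-12)

    def test_mg_zero_level_never_docks(self, canonical):
        sc = replace(canonical, n_frames=100)
        ds = make_titration_dataset(sc, "mg", [0.0], 5, seed=3)
        assert ds.ground_truth.iloc[0].k_dock == 0.0
        for tr in ds.traces[0.0]:
            assert np.all(tr.meta["true_states"] == 0)

    def test_ground_truth_consistent_with_rates(self, canonical):
        sc = replace(canonical, n_frames=50)
        ds = make_titration_dataset(sc, "mg", [2.0, 7.5], 2, seed=4)
        for _, row in ds.ground_truth.iterrows():
            assert row.docked_fraction == pytest.approx(
                row.k_dock / (row.k_dock + row.k_undock)
            )

    def test_dataset_seed_determinism(self, canonical):
        sc = replace(canonical, n_frames=60)
        a = make_titration_dataset(sc, "tRNA", [40.0], 3, seed=9)
        b = make_titration_dataset(sc, "tRNA", [40.0], 3, seed=9)
        for ta, tb in zip(a.traces[40.0], b.traces[40.0]):
            assert np.array_equal(ta.donor, tb.donor)
            assert np.array_equal(ta.acceptor, tb.acceptor)
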