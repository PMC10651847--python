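"""Two-state hidden Markov idealization of FRET traces and dwell-time kinetics.

A Gaussian-emission HMM with parameters shared across all traces of a
condition is trained by expectation-maximization (multiple seeded restarts),
each trace is idealized with the Viterbi algorithm, dwell times are read off
the idealized paths (first/last dwell of each trace censored), and the
docking/undocking rate constants come from maximum-likelihood exponential
(mixture) fits of the dwell-time distributions with a dead-time correction.

Frame-wise transition probabilities are only ever used for initialization;
reported rates always come from the dwell-time fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy import stats

from .errors import ConvergenceError, EmptyInputError, InvalidParameterError
from .traces import FretTrace

__all__ = [
    "HmmModel",
    "DwellSet",
    "DwellFit",
    "RateEstimate",
    "fit_hmm",
    "viterbi_paths",
    "extract_dwells",
    "fit_dwell_distribution",
    "estimate_rates",
    "state_occupancy",
]


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class HmmModel:
    """Trained Gaussian-emission HMM (states sorted by ascending emission mean)."""

    n_states: int
    emission_means: np.ndarray
    emission_sds: np.ndarray
    transition_matrix: np.ndarray   # per-frame probabilities, rows sum to 1
    start_prob: np.ndarray
    log_likelihood: float
    frame_dt: float
    converged: bool = True
    degenerate: bool = False        # a state is unoccupied or states overlap within 1 sd

    def rate_init(self) -> tuple[float, float]:
        """Rates implied by the frame transition probabilities, k = −ln(1−p)/dt.

        Initialization aid only; final rates come from dwell fits.
        """
        p01 = min(self.transition_matrix[0, 1], 1 - 1e-12)
        p10 = min(self.transition_matrix[1, 0], 1 - 1e-12)
        return (-np.log1p(-p01) / self.frame_dt, -np.log1p(-p10) / self.frame_dt)


@dataclass
class DwellSet:
    """Dwell durations per state with censoring flags and trace bookkeeping.

    ``censored`` marks first/last dwells of each trace (excluded from the
    dwell-time distributions); ``end_censored`` marks only dwells terminated
    by the window end or bleaching rather than by an observed transition —
    these enter rate fits as right-censored survival terms, while first
    dwells (which end with a real transition and, for exponential sojourns,
    are valid residual-time samples) enter as complete observations.
    """

    durations: np.ndarray   # seconds
    states: np.ndarray      # state index of each dwell
    censored: np.ndarray    # True for the first/last dwell of a trace
    trace_ids: np.ndarray
    frame_dt: float
    end_censored: np.ndarray | None = None

    def __post_init__(self):
        if self.end_censored is None:
            self.end_censored = np.zeros_like(self.censored)

    def uncensored(self, state: int) -> np.ndarray:
        m = (self.states == state) & (~self.censored)
        return self.durations[m]

    def complete(self, state: int) -> np.ndarray:
        """Dwells of ``state`` ending in an observed transition (fit sample)."""
        m = (self.states == state) & (~self.end_censored)
        return self.durations[m]

    def survival(self, state: int) -> np.ndarray:
        """Right-censored dwells of ``state`` (window/bleach terminated)."""
        m = (self.states == state) & self.end_censored
        return self.durations[m]

    @property
    def dwells_low(self) -> np.ndarray:
        return self.uncensored(0)

    @property
    def dwells_high(self) -> np.ndarray:
        return self.uncensored(1)


@dataclass
class DwellFit:
    """Exponential(-mixture) fit of a dwell-time distribution."""

    rates: np.ndarray
    weights: np.ndarray
    n_components: int
    log_likelihood: float
    n_dwells: int
    dead_time: float
    flags: list = field(default_factory=list)

    @property
    def dominant_rate(self) -> float:
        return float(self.rates[int(np.argmax(self.weights))])


@dataclass
class RateEstimate:
    """Docking/undocking rate constants with bootstrap confidence intervals."""

    k_dock: float | None
    k_undock: float | None
    ci_dock: tuple[float, float] | None
    ci_undock: tuple[float, float] | None
    n_transitions: int
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# HMM training and decoding
# ---------------------------------------------------------------------------

def _prebleach_observations(fret_traces: list[FretTrace]):
    """Finite pre-bleach efficiency segments (>= 5 frames) with their sources."""
    segs, ids = [], []
    for ft in fret_traces:
        e = ft.prebleach_efficiency()
        if e.size >= 5:
            segs.append(e)
            ids.append(ft.molecule_id)
    return segs, ids


def _sorted_model(model: GaussianHMM) -> GaussianHMM:
    """Relabel states so emission means ascend."""
    order = np.argsort(model.means_.ravel())
    model.means_ = model.means_[order]
    # the getter materializes full matrices; the setter wants the diagonals
    diag = np.asarray([np.diag(c) for c in model.covars_])
    model.covars_ = diag[order]
    model.startprob_ = model.startprob_[order]
    model.transmat_ = model.transmat_[np.ix_(order, order)]
    return model


def fit_hmm(
    fret_traces: list[FretTrace],
    n_states: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
) -> tuple[HmmModel, list[np.ndarray]]:
    """Train a shared Gaussian HMM on all pre-bleach segments and decode each.

    EM runs to a relative log-likelihood tolerance of 1e-6 with ``n_restarts``
    seeded random restarts (means drawn around data quantiles); the best model
    by log-likelihood wins. Returns the model (states ascending by mean) and
    one Viterbi path per usable trace, in the order of the usable traces.
    """
    segs, _ = _prebleach_observations(fret_traces)
    if not segs:
        raise EmptyInputError("no usable pre-bleach segments")
    X = np.concatenate(segs)[:, None]
    lengths = [s.size for s in segs]
    n_obs = X.size
    tol = 1e-6 * n_obs  # hmmlearn's tol is absolute in log-likelihood

    rng = np.random.default_rng(seed)
    lo, hi = np.quantile(X, [0.15, 0.85])
    data_var = max(float(np.var(X)), 1e-6)

    best = None
    best_ll = -np.inf
    any_converged = False
    for _ in range(max(1, n_restarts)):
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            init_params="",
            params="stmc",
            random_state=int(rng.integers(2**31 - 1)),
        )
        means = np.sort(rng.uniform(lo, hi, size=n_states))
        model.means_ = means[:, None]
        model.covars_ = np.full((n_states, 1), data_var / max(n_states, 2))
        model.startprob_ = np.full(n_states, 1.0 / n_states)
        stay = rng.uniform(0.8, 0.99)
        tm = np.full((n_states, n_states), (1 - stay) / max(n_states - 1, 1))
        np.fill_diagonal(tm, stay)
        model.transmat_ = tm
        try:
            model.fit(X, lengths)
        except Exception:
            continue
        ll = model.score(X, lengths)
        any_converged = any_converged or model.monitor_.converged
        if ll > best_ll:
            best_ll = ll
            best = model

    if best is None:
        raise ConvergenceError("EM failed on all restarts")
    best = _sorted_model(best)

    paths = viterbi_paths(best, segs)
    occ = np.bincount(np.concatenate(paths), minlength=n_states) / n_obs
    means = best.means_.ravel()
    sds = np.sqrt(np.asarray([np.ravel(c)[0] for c in best.covars_]))
    degenerate = bool(np.any(occ < 0.02)) or bool(
        n_states > 1 and np.any(np.diff(means) < np.maximum(sds[:-1], sds[1:]))
    )
    hmm = HmmModel(
        n_states=n_states,
        emission_means=means,
        emission_sds=sds,
        transition_matrix=best.transmat_,
        start_prob=best.startprob_,
        log_likelihood=float(best_ll),
        frame_dt=fret_traces[0].frame_dt,
        converged=any_converged,
        degenerate=degenerate,
    )
    if not any_converged:
        raise ConvergenceError("EM did not converge within the iteration budget", best_model=(hmm, paths))
    return hmm, paths


def viterbi_paths(model: GaussianHMM, segments: list[np.ndarray]) -> list[np.ndarray]:
    """Most-probable state path for each 1-D observation segment."""
    X = np.concatenate(segments)[:, None]
    lengths = [s.size for s in segments]
    flat = model.predict(X, lengths)
    out, i = [], 0
    for n in lengths:
        out.append(flat[i : i + n])
        i += n
    return out


def state_occupancy(paths: list[np.ndarray], state: int = 1) -> float:
    """Pooled fraction of idealized frames assigned to ``state``."""
    if not paths:
        raise EmptyInputError("no paths")
    total = sum(p.size for p in paths)
    hits = sum(int(np.sum(p == state)) for p in paths)
    return hits / total


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def extract_dwells(paths: list[np.ndarray], frame_dt: float) -> DwellSet:
    """Run lengths of the idealized paths as dwell times.

    The first and last dwell of every trace are censored: their true duration
    is cut by the observation window (or bleaching) and they are excluded
    from distribution fits.
    """
    if frame_dt <= 0:
        raise InvalidParameterError("frame_dt must be positive")
    durs, sts, cens, ends, tids = [], [], [], [], []
    for tid, path in enumerate(paths):
        if path.size == 0:
            continue
        change = np.flatnonzero(np.diff(path)) + 1
        bounds = np.concatenate(([0], change, [path.size]))
        run_lengths = np.diff(bounds)
        run_states = path[bounds[:-1]]
        n_runs = run_lengths.size
        for j in range(n_runs):
            durs.append(run_lengths[j] * frame_dt)
            sts.append(run_states[j])
            cens.append(j == 0 or j == n_runs - 1)
            ends.append(j == n_runs - 1)
            tids.append(tid)
    return DwellSet(
        durations=np.asarray(durs, dtype=float),
        states=np.asarray(sts, dtype=int),
        censored=np.asarray(cens, dtype=bool),
        trace_ids=np.asarray(tids, dtype=int),
        frame_dt=frame_dt,
        end_censored=np.asarray(ends, dtype=bool),
    )


def _exp_mixture_loglik(t: np.ndarray, c: np.ndarray,
                        rates: np.ndarray, weights: np.ndarray) -> float:
    """Log-likelihood of complete dwells ``t`` plus right-censored dwells ``c``."""
    ll = 0.0
    if t.size:
        dens = np.sum(weights[None, :] * rates[None, :] * np.exp(-np.outer(t, rates)), axis=1)
        ll += float(np.sum(np.log(np.clip(dens, 1e-300, None))))
    if c.size:
        surv = np.sum(weights[None, :] * np.exp(-np.outer(c, rates)), axis=1)
        ll += float(np.sum(np.log(np.clip(surv, 1e-300, None))))
    return ll


def _fit_exp_mixture(t: np.ndarray, c: np.ndarray, n_components: int, seed: int = 0):
    """ML exponential-mixture fit of dead-time-shifted dwells via EM.

    ``t`` are complete dwells, ``c`` right-censored ones (observation cut by
    the window or bleaching); censored dwells contribute survival terms, the
    standard correction that removes the finite-window bias of slow rates.
    """
    if n_components == 1:
        # censored-ML closed form: events / total time at risk
        k = t.size / max(float(t.sum() + c.sum()), 1e-12)
        k = np.array([max(k, 1e-12)])
        return k, np.array([1.0]), _exp_mixture_loglik(t, c, k, np.array([1.0]))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(5):
        qs = np.quantile(t, np.linspace(0.2, 0.9, n_components))
        rates = 1.0 / np.clip(qs * rng.uniform(0.5, 2.0, n_components), 1e-9, None)
        weights = np.full(n_components, 1.0 / n_components)
        ll_old = -np.inf
        for _ in range(500):
            dens_k = weights[None, :] * rates[None, :] * np.exp(-np.outer(t, rates))
            tot_t = np.clip(dens_k.sum(axis=1, keepdims=True), 1e-300, None)
            resp_t = dens_k / tot_t
            if c.size:
                surv_k = weights[None, :] * np.exp(-np.outer(c, rates))
                tot_c = np.clip(surv_k.sum(axis=1, keepdims=True), 1e-300, None)
                resp_c = surv_k / tot_c
            else:
                resp_c = np.zeros((0, n_components))
            n_all = t.size + c.size
            weights = (resp_t.sum(axis=0) + resp_c.sum(axis=0)) / n_all
            at_risk = (resp_t * t[:, None]).sum(axis=0) + (resp_c * c[:, None]).sum(axis=0)
            rates = np.clip(resp_t.sum(axis=0) / np.clip(at_risk, 1e-300, None), 1e-9, 1e9)
            ll = _exp_mixture_loglik(t, c, rates, weights)
            if ll - ll_old < 1e-10 * max(abs(ll), 1.0):
                break
            ll_old = ll
        if best is None or ll > best[2]:
            best = (rates, weights, ll)
    rates, weights, ll = best
    order = np.argsort(rates)
    return rates[order], weights[order], ll


def fit_dwell_distribution(
    dwells: np.ndarray,
    n_components: int = 2,
    dead_time: float | None = None,
    frame_dt: float = 0.1,
    seed: int = 0,
    censored: np.ndarray | None = None,
) -> DwellFit:
    """Maximum-likelihood exponential(-mixture) fit of dwell times.

    Complete dwells shorter than the dead time (2 frames by default; events
    this short are unreliably detected) are dropped and the remainder shifted
    by it, so the fit is of a left-truncated exponential. ``censored``
    durations (first/last dwells, cut by the observation window or
    bleaching) enter as right-censored survival terms — without them the
    rates of slow processes are overestimated because long dwells
    preferentially hit the window edges. With ``n_components=2`` a
    likelihood-ratio test (α = 0.05, 2 extra parameters) decides whether the
    second component is justified; the dominant-weight component is the
    reported rate either way.

    Fewer than 50 complete dwells yields a flagged estimate from the
    censored-ML closed form (events / total time at risk) rather than a
    mixture fit.
    """
    dwells = np.asarray(dwells, dtype=float)
    t0 = 2 * frame_dt if dead_time is None else dead_time
    use = dwells[dwells >= t0] - t0
    cens = np.clip(np.asarray(censored, dtype=float) - t0, 0.0, None) \
        if censored is not None and len(censored) else np.zeros(0)
    n = use.size
    if n == 0:
        return DwellFit(np.array([np.nan]), np.array([1.0]), 1, np.nan, 0, t0,
                        flags=["insufficient-data"])
    if n < 50:
        r1, w1, ll1 = _fit_exp_mixture(use, cens, 1)
        return DwellFit(r1, w1, 1, ll1, n, t0, flags=["insufficient-data"])
    if float(np.std(use)) == 0.0:
        r1, w1, ll1 = _fit_exp_mixture(use, cens, 1)
        return DwellFit(r1, w1, 1, ll1, n, t0, flags=["insufficient-variance"])

    r1, w1, ll1 = _fit_exp_mixture(use, cens, 1)
    if n_components == 1:
        return DwellFit(r1, w1, 1, ll1, n, t0)
    r2, w2, ll2 = _fit_exp_mixture(use, cens, 2, seed=seed)
    # LRT with one extra (rate, weight) pair
    p = stats.chi2.sf(2 * (ll2 - ll1), df=2)
    if p < 0.05:
        return DwellFit(r2, w2, 2, ll2, n, t0)
    return DwellFit(r1, w1, 1, ll1, n, t0, flags=["single-exponential-preferred"])


def estimate_rates(
    dwellset: DwellSet,
    frame_dt: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> RateEstimate:
    """Docking/undocking rates from dwell-time fits with bootstrap CIs.

    k_dock is the dominant rate of the undocked (low-FRET) dwell distribution,
    k_undock of the docked (high-FRET) one. Confidence intervals are 2.5–97.5
    percentile over ``n_boot`` resamples of whole traces.
    """
    dt = dwellset.frame_dt if frame_dt is None else frame_dt
    flags: list[str] = []

    def _point(s: int) -> float | None:
        durations = dwellset.complete(s)
        if durations.size == 0:
            return None
        fit = fit_dwell_distribution(durations, 2, frame_dt=dt, seed=seed + s,
                                     censored=dwellset.survival(s))
        flags.extend(f"state{s}:{f}" for f in fit.flags)
        return fit.dominant_rate if np.isfinite(fit.dominant_rate) else None

    k_dock = _point(0)
    k_undock = _point(1)
    if k_dock is None:
        flags.append("missing-rate:k_dock")
    if k_undock is None:
        flags.append("missing-rate:k_undock")

    n_transitions = int(np.sum(~dwellset.censored))

    rng = np.random.default_rng(seed)
    unique_ids = np.unique(dwellset.trace_ids)
    boot = {0: [], 1: []}
    if unique_ids.size > 1 and n_boot > 0:
        for _ in range(n_boot):
            pick = rng.choice(unique_ids, size=unique_ids.size, replace=True)
            mask_parts = [np.flatnonzero(dwellset.trace_ids == tid) for tid in pick]
            idx = np.concatenate(mask_parts) if mask_parts else np.array([], dtype=int)
            for s in (0, 1):
                m = dwellset.states[idx] == s
                comp = m & (~dwellset.end_censored[idx])
                d = dwellset.durations[idx][comp]
                d = d[d >= 2 * dt] - 2 * dt
                c = np.clip(dwellset.durations[idx][m & dwellset.end_censored[idx]] - 2 * dt,
                            0, None)
                if d.size:
                    # censored-ML closed form: events / time at risk
                    boot[s].append(d.size / max(float(d.sum() + c.sum()), 1e-12))

    def _ci(vals: list, point) -> tuple[float, float] | None:
        if point is None or len(vals) < 20:
            return None
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return (float(lo), float(hi))

    return RateEstimate(
        k_dock=k_dock,
        k_undock=k_undock,
        ci_dock=_ci(boot[0], k_dock),
        ci_undock=_ci(boot[1], k_undock),
        n_transitions=n_transitions,
        flags=flags,
    )
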