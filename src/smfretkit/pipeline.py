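"""Condition- and titration-level orchestration of the analysis chain.

Glues the stages together the way a measurement is actually processed:
intensity traces → efficiency + bleach annotation → selection → shared HMM →
Viterbi occupancy and dwell-time kinetics → titration fit. Each helper
returns plain containers from the stage modules so any step can be rerun or
swapped in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntensityTrace
from .errors import ConvergenceError
from .idealize import (DwellSet, HmmModel, RateEstimate, estimate_rates,
                       extract_dwells, fit_hmm, state_occupancy, viterbi_paths)
from .synth import TitrationDataset
from .thermofit import TitrationFit, binding_fit, hill_fit
from .traces import FretTrace, SelectionConfig, analyze_trace, select_traces

__all__ = ["ConditionResult", "analyze_condition", "titration_occupancy", "fit_titration"]


@dataclass
class ConditionResult:
    """Everything the pipeline derives from one condition's trace set."""

    fret_traces: list
    accepted: list
    model: HmmModel | None
    paths: list
    occupancy: float
    dwells: DwellSet | None
    rates: RateEstimate | None
    n_accepted: int
    n_total: int


def analyze_condition(
    traces: list[IntensityTrace],
    seed: int = 0,
    selection: SelectionConfig | None = None,
    with_rates: bool = True,
    n_restarts: int = 10,
) -> ConditionResult:
    """Select, idealize and (optionally) extract kinetics for one condition.

    When the trained HMM is degenerate (effectively one state), occupancy
    falls back to thresholding at the midpoint of the two emission means —
    blur-robust and well-defined even when one state is barely visited.
    """
    fret = [analyze_trace(t, selection) for t in traces]
    accepted = select_traces(fret, selection)
    if not accepted:
        return ConditionResult(fret, [], None, [], np.nan, None, None, 0, len(traces))

    try:
        model, paths = fit_hmm(accepted, n_states=2, seed=seed, n_restarts=n_restarts)
    except ConvergenceError as exc:
        if exc.best_model is None:
            raise
        model, paths = exc.best_model

    occ = state_occupancy(paths, state=1)
    if model.degenerate:
        lo, hi = model.emission_means[0], model.emission_means[-1]
        if 0 < hi - lo < max(model.emission_sds.max(), 1e-3):
            # states collapsed onto one peak: the Viterbi split is arbitrary,
            # so classify frames against the midpoint instead
            pooled = np.concatenate([ft.prebleach_efficiency() for ft in accepted])
            occ = float(np.mean(pooled > 0.5 * (lo + hi)))

    dwells = rates = None
    if with_rates:
        dwells = extract_dwells(paths, model.frame_dt)
        rates = estimate_rates(dwells, seed=seed)
    return ConditionResult(fret, accepted, model, paths, float(occ),
                           dwells, rates, len(accepted), len(traces))


def titration_occupancy(
    dataset: TitrationDataset,
    seed: int = 0,
    with_rates: bool = False,
    n_restarts: int = 10,
    train_per_level: int = 80,
) -> pd.DataFrame:
    """Per-level docked-state occupancy via the selection + HMM pipeline.

    The two emission states are a property of the molecule, not of the
    concentration, so one HMM is trained on traces pooled across all levels
    (a per-level subsample of up to ``train_per_level`` accepted traces keeps
    EM affordable) and each level is then decoded with the shared model.
    This keeps both states anchored at extreme levels where one state is
    nearly unvisited and a per-level fit would latch onto noise.

    Returns a table with one row per concentration level: the estimated
    docked fraction, acceptance counts, and (optionally) dwell-fit rates.
    """
    accepted_by_level: dict[float, list[FretTrace]] = {}
    for lev in dataset.levels:
        fret = [analyze_trace(t) for t in dataset.traces[float(lev)]]
        accepted_by_level[float(lev)] = select_traces(fret)

    train_pool: list[FretTrace] = []
    for lev in dataset.levels:
        train_pool.extend(accepted_by_level[float(lev)][:train_per_level])
    if not train_pool:
        raise ConvergenceError("no accepted traces in the whole titration")
    try:
        model, _ = fit_hmm(train_pool, n_states=2, seed=seed, n_restarts=n_restarts)
    except ConvergenceError as exc:
        if exc.best_model is None:
            raise
        model, _ = exc.best_model

    gm = _as_hmmlearn(model)
    rows = []
    for lev in dataset.levels:
        acc = accepted_by_level[float(lev)]
        row = {"level": float(lev), "docked_fraction": np.nan,
               "n_accepted": len(acc), "n_total": len(dataset.traces[float(lev)])}
        if acc:
            segs = [ft.prebleach_efficiency() for ft in acc]
            segs = [s for s in segs if s.size >= 5]
            paths = viterbi_paths(gm, segs)
            row["docked_fraction"] = state_occupancy(paths, state=1)
            if with_rates:
                dwells = extract_dwells(paths, model.frame_dt)
                rates = estimate_rates(dwells, seed=seed)
                row["k_dock"] = rates.k_dock
                row["k_undock"] = rates.k_undock
        rows.append(row)
    return pd.DataFrame(rows)


def _as_hmmlearn(model: HmmModel):
    """Rebuild an hmmlearn GaussianHMM from a trained HmmModel for decoding."""
    from hmmlearn.hmm import GaussianHMM

    gm = GaussianHMM(n_components=model.n_states, covariance_type="diag", init_params="")
    gm.means_ = model.emission_means[:, None]
    gm.covars_ = (model.emission_sds**2)[:, None]
    gm.startprob_ = model.start_prob
    gm.transmat_ = model.transition_matrix
    return gm


def fit_titration(table: pd.DataFrame, axis: str) -> TitrationFit:
    """Hill fit (axis='mg') or isotherm fit (axis='tRNA') of an occupancy table."""
    fitter = hill_fit if axis == "mg" else binding_fit
    return fitter(table["level"].to_numpy(), table["docked_fraction"].to_numpy())
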