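"""Thermodynamic readouts: Gaussian decomposition of FRET histograms,
Hill/isotherm titration fits, and free-energy landscapes from rate constants.

State populations come from either of two estimators the pipeline provides —
Gaussian-component areas of the pooled histogram, or HMM-path occupancy — and
titration curves of the docked-state fraction are fitted with the Hill
equation (Mg²⁺ axis, free Hill coefficient) or a 1:1 binding isotherm (tRNA
axis). Free energies follow ΔG_b − ΔG_a = −k_B·T·ln(k_a→b / k_b→a) with the
low-FRET (undocked) state as the ground state, and barrier heights use the
illustration convention −k_B·T·ln(k) + 1.8·k_B·T (relative, arbitrary
pre-exponential).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, FitError, InvalidParameterError
from .idealize import RateEstimate
from .traces import FretHistogram

__all__ = [
    "MixtureFit",
    "TitrationFit",
    "EnergyLandscape",
    "fit_mixture",
    "hill_fit",
    "binding_fit",
    "free_energy_landscape",
    "KB_KCAL",
]

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL = 0.001987204


# ---------------------------------------------------------------------------
# Gaussian mixture decomposition of histograms
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Sum-of-Gaussians decomposition of a FRET histogram."""

    centers: np.ndarray
    widths: np.ndarray
    fractions: np.ndarray   # component areas normalized to sum 1
    amplitudes: np.ndarray  # density amplitudes
    fit_rmse: float

    def fraction_above(self, index: int) -> float:
        return float(self.fractions[index])


def _gauss_sum(x, *params):
    n = len(params) // 3
    y = np.zeros_like(x, dtype=float)
    for i in range(n):
        a, c, w = params[3 * i : 3 * i + 3]
        y = y + a * np.exp(-((x - c) ** 2) / (2 * w**2))
    return y


def fit_mixture(
    hist: FretHistogram,
    n_states: int = 2,
    init: np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Nonlinear least-squares fit of ``n_states`` Gaussians to the histogram density.

    Component fractions are areas divided by the total area. Five multistart
    inits (quantile-anchored centers with jitter, or the user's ``init``
    centers) guard against local minima; the lowest-RMSE fit wins.
    """
    x = hist.bin_centers
    y = hist.density()
    occupied = int(np.sum(y > 0))
    if n_states >= 2 and occupied < 20:
        raise InvalidParameterError("need >= 20 occupied bins for a multi-state fit")

    rng = np.random.default_rng(seed)
    # effective samples per bin for weighting are unknown after normalization;
    # plain (unweighted) least squares on the density is used throughout
    mass = np.clip(y, 0, None) / max(np.sum(y), 1e-300)
    mean_e = float(np.sum(x * mass))
    sd_e = float(np.sqrt(np.sum((x - mean_e) ** 2 * mass))) or 0.05

    cum = np.cumsum(mass)
    quantile_centers = np.interp(np.linspace(0.15, 0.85, n_states), cum, x)

    best = None
    errors = []
    for s in range(max(1, n_starts)):
        if init is not None and s == 0:
            centers0 = np.sort(np.asarray(init, dtype=float))
        else:
            centers0 = np.sort(quantile_centers + rng.normal(0, 0.3 * sd_e / max(n_states, 1), n_states))
        p0 = []
        for c in centers0:
            p0 += [float(max(y.max(), 1e-6)) / n_states, float(c), max(0.5 * sd_e / np.sqrt(n_states), 0.02)]
        lb = [0.0, x.min(), 1e-3] * n_states
        ub = [np.inf, x.max(), (x.max() - x.min())] * n_states
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
        except Exception as exc:  # pragma: no cover - diagnostics path
            errors.append(str(exc))
            continue
        resid = y - _gauss_sum(x, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        if best is None or rmse < best[1]:
            best = (popt, rmse)
    if best is None:
        raise FitError("Gaussian mixture fit failed on all starts", details={"errors": errors})

    popt, rmse = best
    amps = np.asarray(popt[0::3])
    centers = np.asarray(popt[1::3])
    widths = np.asarray(popt[2::3])
    order = np.argsort(centers)
    amps, centers, widths = amps[order], centers[order], widths[order]
    areas = amps * widths * np.sqrt(2 * np.pi)
    fractions = areas / areas.sum() if areas.sum() > 0 else np.full(n_states, np.nan)
    return MixtureFit(centers=centers, widths=widths, fractions=fractions,
                      amplitudes=amps, fit_rmse=rmse)


# ---------------------------------------------------------------------------
# titration fits
# ---------------------------------------------------------------------------

@dataclass
class TitrationFit:
    """Fitted titration curve of the docked-state fraction."""

    axis: str                     # "mg" or "tRNA"
    levels: np.ndarray
    fractions: np.ndarray
    midpoint: float               # [Mg2+]1/2 in mM, or K_d in nM
    se_midpoint: float
    hill_n: float | None          # mg axis only
    f0: float
    f_inf: float
    covariance: np.ndarray
    extrapolated: bool = False

    def predict(self, levels: np.ndarray) -> np.ndarray:
        lev = np.asarray(levels, dtype=float)
        n = 1.0 if self.hill_n is None else self.hill_n
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(lev > 0, lev**n / (lev**n + self.midpoint**n), 0.0)
        return self.f0 + (self.f_inf - self.f0) * h


def _titration_fit(levels, fractions, axis: str, fix_n: float | None) -> TitrationFit:
    levels = np.asarray(levels, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if levels.size < 4:
        raise InvalidParameterError("need at least 4 titration levels")
    if np.any(levels < 0):
        raise InvalidParameterError("levels must be >= 0")
    if float(np.ptp(fractions)) < 1e-12:
        raise DegenerateFitError("fractions are constant; midpoint is unidentifiable")

    f0_guess = float(fractions.min())
    finf_guess = float(fractions.max())
    half = f0_guess + 0.5 * (finf_guess - f0_guess)
    m_guess = float(np.interp(half, fractions, levels)) if np.all(np.diff(fractions) >= 0) \
        else float(np.median(levels[levels > 0]))
    m_guess = max(m_guess, float(np.min(levels[levels > 0])) * 0.5)

    if fix_n is None:
        def f(x, m, n, f0, finf):
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.where(x > 0, x**n / (x**n + m**n), 0.0)
            return f0 + (finf - f0) * h
        p0 = [m_guess, 1.5, f0_guess, finf_guess]
        bounds = ([1e-9, 0.2, -0.5, -0.5], [np.inf, 10.0, 1.5, 1.5])
    else:
        def f(x, m, f0, finf):
            h = x / (x + m)
            return f0 + (finf - f0) * h
        p0 = [m_guess, f0_guess, finf_guess]
        bounds = ([1e-9, -0.5, -0.5], [np.inf, 1.5, 1.5])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(f, levels, fractions, p0=p0, bounds=bounds, maxfev=20000)
    midpoint = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    hill_n = float(popt[1]) if fix_n is None else None
    f0, finf = (float(popt[2]), float(popt[3])) if fix_n is None else (float(popt[1]), float(popt[2]))

    pos = levels[levels > 0]
    extrapolated = not (pos.min() <= midpoint <= pos.max())
    if extrapolated:
        warnings.warn("fitted midpoint lies outside the sampled concentration range", stacklevel=2)
    return TitrationFit(axis=axis, levels=levels, fractions=fractions, midpoint=midpoint,
                        se_midpoint=se, hill_n=hill_n, f0=f0, f_inf=finf,
                        covariance=pcov, extrapolated=extrapolated)


def hill_fit(levels, fractions) -> TitrationFit:
    """Hill fit of docked fraction vs Mg²⁺ (midpoint in mM, free Hill coefficient).

    f(mg) = f₀ + (f∞ − f₀)·mgⁿ/(mgⁿ + m½ⁿ), least squares; the midpoint
    standard error comes from the fit covariance.
    """
    return _titration_fit(levels, fractions, "mg", fix_n=None)


def binding_fit(levels, fractions) -> TitrationFit:
    """1:1 binding-isotherm fit of docked fraction vs [tRNA] (K_d in nM)."""
    return _titration_fit(levels, fractions, "tRNA", fix_n=1.0)


# ---------------------------------------------------------------------------
# free-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class EnergyLandscape:
    """Relative free energies (kcal/mol) of the two-state system.

    The undocked (low-FRET) state is the ground state (ΔG = 0). Barrier
    heights use an arbitrary pre-exponential and are only comparable across
    conditions analyzed with the same convention.
    """

    dG_states: np.ndarray          # (undocked, docked)
    barrier_heights: np.ndarray    # (undocked->docked, docked->undocked)
    temperature: float
    kBT: float


def free_energy_landscape(rates: RateEstimate, temperature: float = 298.15) -> EnergyLandscape:
    """Two-state free-energy landscape from the rate constants.

    ΔG_docked − ΔG_undocked = −k_B·T·ln(k_dock/k_undock); the barrier out of
    state a is −k_B·T·ln(k_a→b) + 1.8·k_B·T (illustration convention).
    """
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive")
    k_dock, k_undock = rates.k_dock, rates.k_undock
    if k_dock is None or k_undock is None or k_dock <= 0 or k_undock <= 0:
        raise InvalidParameterError("both rates must be positive")
    kbt = KB_KCAL * temperature
    dg_docked = -kbt * np.log(k_dock / k_undock)
    # per-transition barriers measured from the departing state
    barrier_dock = -kbt * np.log(k_dock) + 1.8 * kbt
    barrier_undock = -kbt * np.log(k_undock) + 1.8 * kbt
    return EnergyLandscape(
        dG_states=np.array([0.0, dg_docked]),
        barrier_heights=np.array([barrier_dock, barrier_undock]),
        temperature=temperature,
        kBT=kbt,
    )
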