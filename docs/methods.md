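# Methods

This note records the models, estimators, defaults and numerical choices
behind `smfretkit`, and what the synthetic-data tests do and do not
establish about real data.

## Kinetic model and synthetic data

Docking is a continuous-time two-state Markov process. `synth` samples exact
Gillespie realizations (exponential sojourns; initial state drawn from the
stationary distribution unless pinned) and renders camera traces by
integrating the state's FRET efficiency over each 100 ms frame, so an event
inside a frame produces an intermediate "blurred" value, as on a real
camera. On top of the time-averaged efficiency each frame receives

- per-state Gaussian efficiency noise (default sd 0.06 per state — the
  published histograms resolve states ~0.1 apart with widths of this order,
  but no widths are printed, so this is a package default),
- channel intensities I_A = I_tot·E, I_D = I_tot·(1−E) with Poisson shot
  noise and Gaussian read noise (I_tot = 1000 counts/frame, read sd 10,
  gain 1 — only ratios matter downstream),
- independent exponential photobleaching clocks per dye (default
  0.01 s⁻¹ each, giving ≈ 400 usable frames per molecule on average,
  matching experiments that average > 250 pre-bleach frames). Acceptor
  bleach moves the intensity to the donor channel and drops the apparent
  efficiency to a donor-only baseline of 0.05 rather than 0, so bleach
  detection is actually exercised; donor bleach darkens both channels.

Because the efficiency (not each channel independently) fluctuates, donor
and acceptor are anticorrelated even for a static molecule — the property
the trace-selection step keys on, and true of real data for the same reason.

**Mg²⁺ dependence.** The published titration midpoint is defined on the
*occupancy* curve (the concentration of half-maximal docked fraction), so
the generator parameterizes the Mg²⁺ axis that way: the stationary docked
fraction follows f(mg) = f_max·mgⁿ/(mgⁿ + mg_half ⁿ) with
f_max = k_dock_max/(k_dock_max + k_undock), and the per-level docking rate
is derived as k_dock = k_undock·f/(1−f) with k_undock held Mg-independent
(its published value varies only within 0.19–0.26 s⁻¹ over the titration).
The standalone `mg_dependent_dock_rate` op applies the Hill form to the
rate itself, which is the observed qualitative behavior of k_dock; note the
two conventions coincide only in the weak-docking limit. The tRNA axis is
pseudo-first-order binding, k_dock = k_on·[tRNA], k_undock = k_on·K_d, so
its occupancy is exactly the 1:1 isotherm.

Canonical scenario defaults: FRET means (0.32, 0.57) [undocked/docked
inter-stem reporter], mg_half = 3.9 mM, Hill n = 2 (no coefficient is
printed; 2 is a typical value for Mg²⁺-driven RNA folding and is a free
parameter in all fits), k_undock = 0.22 s⁻¹ (mid-range of the published
band), k_dock_max = 1.0 s⁻¹ (order of magnitude of the fast end of the
published dock rates), K_d = 40 nM, 800 frames × 0.1 s. The deletion
intermediates differ only in mg_half (10.7, 13.2 mM); the intra-stem
reporter uses means (0.45, 0.70).

**Movies.** Each molecule is an isotropic Gaussian spot (σ = 1.2 px) whose
integrated volume per frame equals that frame's channel intensity; donor in
the left half-field, acceptor at the donor position plus a rigid offset in
the right half-field; uniform background, then Poisson and read noise over
the full frame. For movie synthesis the input traces should be *expected*
intensities (scenario with `shot_noise=False`): the camera applies photon
noise once. Sub-4·σ spot spacing is flagged, not forbidden.

**Seeding.** Every stochastic op takes a seed or Generator; dataset seeds
derive per-trace seeds through `numpy.random.SeedSequence.spawn`, so a
dataset is bit-reproducible and traces are independent.

## Localization

Pixel coordinates are 0-based with pixel centers at integers. Detection
runs on the average of the first 20 frames per half-field: local maxima
above median + SNR·(1.4826·MAD), non-maximum suppression within 5 px, 4-px
border margin. Each candidate is refined by a least-squares elliptical
Gaussian + constant fit in a 9×9 window; the background-subtracted volume
2π·A·σx·σy is the intensity observable. Channel registration accumulates
all pairwise acceptor−donor displacement vectors in a 1-px 2D vote
histogram; the transform is the centroid of votes within ±1.5 px of the
modal bin (≥ 3 votes required), and pairs within 2 px of the transform are
matched greedily and uniquely. Only translation is modeled — adequate for
the rigid two-half-field geometry; rotation/magnification are out of scope.

Per-frame intensities are extracted at fixed positions (immobilized
molecules): center and shape come from the average-image fit and are held
constant, so each frame needs only the amplitude and local background,
which solve linearly in closed form. This is faster and lower-variance
than refitting five nonlinear parameters per frame, at the cost of
insensitivity to stage drift (not modeled, and flagged as a limitation for
real data with drift).

At the noise floor the extraction error is set by photon statistics: with
I_tot = 3000 counts/frame and background 20 counts/px the round trip
recovers per-frame intensities to ≈ 4% relative RMS; at I_tot = 1000 and
background 100 it is ≈ 10%. The < 5%-at-SNR ≥ 10 round-trip test uses the
brighter conditions.

## Traces, selection, histograms

E = I_A/(I_A + γ·I_D) with γ = 1 (the study reports apparent efficiencies
and no correction factors; γ is a hook). Frames with total intensity below
10% of the trace median are masked.

Photobleach detection: the largest prefix/suffix mean step of the total
intensity is a donor bleach if the post-step mean is < 25% of the pre-step
mean and the step exceeds 5× the pre-step noise sd. Acceptor-first bleach
conserves the total (photons shift to the donor), so a second scan finds
the onset of the acceptor channel's dark tail — the last time the 5-frame
median exceeds 0.4 of the bright (95th-percentile) level — restricted to
frames before any total-intensity step; a two-segment step model is not
used here because genuine FRET dynamics before the bleach misplace its
change point. The earliest valid step wins. On canonical synthetic traces
the detector is exact to ±1 frame for > 95% of bleaches.

Selection accepts a trace iff, over pre-bleach frames: both channel means
exceed the intensity floor, Pearson r(I_D, I_A) ≤ −0.2, any bleach is a
clean single-dye signature, and ≥ 50 frames remain. Thresholds are
package defaults exposed in `SelectionConfig`, not values inferred from the
study (which published no numbers for its manual picking).

Histograms pool pre-bleach frames of accepted traces, bin width 0.02 over
[−0.1, 1.1] (resolves the closest published peak pair, 0.08 vs 0.16), and
are normalized by total frame count so bins are probabilities.

## Idealization and kinetics

One Gaussian-emission HMM per condition (or per titration, see below) is
trained by EM on all accepted pre-bleach segments: 10 seeded restarts with
quantile-anchored random means, relative log-likelihood tolerance 1e-6,
≤ 500 iterations, states relabeled ascending by emission mean; decoding is
per-trace Viterbi. EM and Viterbi are delegated to `hmmlearn`; the test
suite checks Viterbi against exhaustive path enumeration on all segments of
length ≤ 12. A model is flagged degenerate when a state's occupancy falls
below 2% or the means collapse within one sd.

For titrations the emission model is shared across *all* levels (trained on
a subsample of up to 80 accepted traces per level, decoded per level):
the states are molecular properties, not per-condition ones, and a
per-level two-state fit invents a second state out of noise at levels where
one state is nearly unvisited (measured bias up to +0.1 occupancy at the
lowest tRNA level, which a shared model removes).

Dwell times are run lengths of the Viterbi paths × frame time. The
distribution lists exclude each trace's first and last dwell; the *rate*
likelihood keeps both — the first dwell ends with an observed transition
and under exponential sojourns its residual duration is a valid sample,
while the last dwell (window- or bleach-terminated) enters as a
right-censored survival term. Without the survival terms, slow rates are
systematically overestimated (+30%/+15%/+7% at k = 0.05/0.1/0.2 s⁻¹ in an
80 s window, measured on exact paths). Fits are maximum-likelihood
exponential mixtures with a 2-frame dead time (left truncation); a
likelihood-ratio test (α = 0.05, 2 df) decides one vs two components, and
the dominant-weight component is the reported rate. Below 50 complete
dwells the closed-form censored estimate (events / time at risk) is
returned flagged instead. Confidence intervals are 2.5–97.5 percentiles
over 200 bootstrap resamples of whole traces using the closed form.
Known degradation: when 1/k approaches the frame time, camera blurring
merges events and rates are underestimated; recovery is ~10% accurate for
dwells ≥ 5 frames and deteriorates below that.

## Populations, titrations, free energy

State populations come from two estimators, both reported: the Viterbi-path
occupancy, and the component-area fractions of a Gaussian-mixture fit to
the pooled histogram density (nonlinear least squares, 5 multistart inits,
lowest RMSE wins; fractions are areas over total area). On 300-trace
synthetic datasets both agree with the generating occupancy within ~2
percentage points; transition-blurred frames pull both slightly toward the
wider component.

Titration fits are plain least squares: the Hill form with free midpoint,
coefficient, f₀ and f∞ for the Mg²⁺ axis, and the 1:1 isotherm (Hill
coefficient fixed at 1) for the tRNA axis. Midpoint standard errors come
from the fit covariance; a midpoint outside the sampled range triggers an
extrapolation warning rather than an error. Both fits are exactly
scale-equivariant in concentration.

Free energies use k_B = 0.001987204 kcal/(mol·K) and T = 298.15 K by
default (measurements at 25 °C): ΔG_docked = −k_B T ln(k_dock/k_undock)
with the undocked state as ground state, and per-transition barriers
−k_B T ln(k) + 1.8 k_B T. The 1.8 k_B T offset is an illustration
convention carried over as-is; barriers are relative (arbitrary
pre-exponential) and only comparable across conditions analyzed
identically.

## SAXS

Guinier: iterated weighted linear fit of ln I vs q² over the largest low-q
window with q·R_g ≤ 1.3 (window grown/shrunk to self-consistency);
R_g = √(−3·slope). Note the Guinier approximation itself biases sphere-like
scatterers by ≈ +2% at the 1.3 cutoff (< 1% at 0.9); the cutoff is a
parameter. Non-negative slope raises an aggregation error.

The dimensionless Kratky transform is exact and pointwise; for ideal
Guinier-form data it peaks at (√3, 3/e), the compactness reference used in
the plots.

P(r): I(q) = 4π∫p(r)·sinc(qr)dr is discretized on a 101-point grid over
[0, D_max] (trapezoid quadrature) and solved by linear least squares with a
second-difference roughness penalty and hard endpoint zeros. The default
q window is 0.006–0.30 Å⁻¹. When no regularization weight is supplied, the
package scans a 25-point logarithmic path and takes the *largest* α whose
reduced χ² stays within max(1.3×, +0.1) of the path minimum — the smoothest
solution consistent with the data. (A curvature-based L-curve corner was
tried first and is numerically unreliable when the χ² axis spans many
decades, e.g. on noiseless analytic fixtures.) R_g and I₀ are also reported
from the p(r) moments; χ²/point > 10 flags an underestimated D_max.

Model scattering is the bare Debye sum over point scatterers with
sin(x)/x → 1 at coincident points, and χ² fits the scale factor
analytically. This deliberately omits excluded-volume and hydration-shell
corrections: it ranks coarse-grained decoys (the use here) but is not on
an absolute scale against experiment.

## What the synthetic tests do and do not show

They establish that every estimator recovers its generating quantity at
realistic noise, trace counts and bleaching, including the full pipeline
compositions (movie → traces, titration → midpoint). They do not exercise:
spectral crosstalk and γ ≠ 1, triplet blinking, stage drift, non-Gaussian
PSFs, non-exponential (molecular-memory) dwells beyond two-component
mixtures, three-state models, or SAXS hydration effects. Conclusions about
real data inherit those caveats.

## Problem sizes

The recovery checks use the study's scale — 300 molecules per condition,
800 frames at 100 ms, six titration levels — which runs in roughly a minute
per titration on one CPU. Examples use 100–150 molecules for snappier
demonstration runs.
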