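"""Spot detection, 2D Gaussian fitting, channel registration and trace
extraction from two-half-field TIRF movies.

Spots are fitted with an elliptical 2D Gaussian plus constant background
inside a 9×9 pixel window; the background-subtracted integrated volume
2π·A·σx·σy is the raw fluorescence intensity. Donor and acceptor half-fields
are registered by accumulating all pairwise displacement vectors into a
voting histogram (the simplest Hough parameterization for a pure
translation). Pixel coordinates are 0-based with pixel centers at integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .core import IntensityTrace
from .errors import AmbiguousRegistrationError, BorderError, InvalidParameterError
from .synth import Movie

__all__ = [
    "SpotFit",
    "ChannelTransform",
    "detect_spots",
    "fit_gaussian_2d",
    "estimate_channel_transform",
    "extract_traces",
    "extract_movie",
]

#: residual sentinel marking a non-converged fit
RESIDUAL_SENTINEL = np.inf

_WIN = 4  # 9x9 window half-size


@dataclass
class SpotFit:
    """Elliptical 2D Gaussian fit of one spot within its 9×9 window."""

    center: tuple[float, float]   # (x, y), sub-pixel
    sigma_x: float
    sigma_y: float
    amplitude: float
    background: float
    residual_rms: float
    converged: bool = True

    @property
    def volume(self) -> float:
        """Background-subtracted integrated intensity, 2π·A·σx·σy."""
        return float(2 * np.pi * self.amplitude * self.sigma_x * self.sigma_y)


@dataclass
class ChannelTransform:
    """Rigid translation mapping donor-spot to acceptor-spot coordinates."""

    dx: float
    dy: float
    n_votes: int
    inlier_fraction: float
    matches: list = field(default_factory=list)  # (donor_idx, acceptor_idx) pairs

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) + np.array([self.dx, self.dy])


# ---------------------------------------------------------------------------
# detection and fitting
# ---------------------------------------------------------------------------

def detect_spots(frame: np.ndarray, min_snr: float = 5.0) -> list[tuple[int, int]]:
    """Candidate spot pixels: local maxima above background + min_snr·noise.

    Background is the frame median, noise the median absolute deviation
    (scaled to sd); maxima within 5 px of a brighter one are suppressed and a
    4-px border margin keeps the subsequent 9×9 fit inside the frame.
    Returns (x, y) integer pixel coordinates; an all-flat frame yields [].
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape[0] < 9 or frame.shape[1] < 9:
        raise InvalidParameterError("frame must be at least 9x9")
    background = float(np.median(frame))
    noise = 1.4826 * float(np.median(np.abs(frame - background)))
    if noise == 0:
        noise = float(np.std(frame))
    if noise == 0:
        return []
    threshold = background + min_snr * noise
    peaks = peak_local_max(
        frame,
        min_distance=5,
        threshold_abs=threshold,
        exclude_border=_WIN,
    )
    return [(int(c), int(r)) for r, c in peaks]


def _gauss2d(coords, amplitude, x0, y0, sx, sy, background):
    x, y = coords
    return (
        amplitude * np.exp(-((x - x0) ** 2) / (2 * sx**2) - ((y - y0) ** 2) / (2 * sy**2))
        + background
    ).ravel()


def fit_gaussian_2d(frame: np.ndarray, seed_pixel: tuple[int, int]) -> SpotFit:
    """Least-squares elliptical-Gaussian + background fit in the 9×9 window.

    ``seed_pixel`` is (x, y). A window clipped by the frame border raises
    :class:`BorderError`; a non-converging fit returns a flagged
    :class:`SpotFit` with ``residual_rms`` set to the sentinel.
    """
    frame = np.asarray(frame, dtype=float)
    x0, y0 = int(round(seed_pixel[0])), int(round(seed_pixel[1]))
    h, w = frame.shape
    if x0 - _WIN < 0 or x0 + _WIN >= w or y0 - _WIN < 0 or y0 + _WIN >= h:
        raise BorderError(f"9x9 window around {seed_pixel} clipped by the frame border")
    win = frame[y0 - _WIN : y0 + _WIN + 1, x0 - _WIN : x0 + _WIN + 1]
    ys, xs = np.mgrid[y0 - _WIN : y0 + _WIN + 1, x0 - _WIN : x0 + _WIN + 1]

    bg0 = float(np.median(win))
    a0 = float(win.max() - bg0)
    p0 = [max(a0, 1e-6), float(x0), float(y0), 1.5, 1.5, bg0]
    bounds = (
        [0.0, x0 - _WIN, y0 - _WIN, 0.3, 0.3, -np.inf],
        [np.inf, x0 + _WIN, y0 + _WIN, 2 * _WIN, 2 * _WIN, np.inf],
    )
    try:
        popt, _ = curve_fit(_gauss2d, (xs, ys), win.ravel(), p0=p0, bounds=bounds, maxfev=5000)
    except RuntimeError:
        return SpotFit(center=(float(x0), float(y0)), sigma_x=p0[3], sigma_y=p0[4],
                       amplitude=0.0, background=bg0,
                       residual_rms=RESIDUAL_SENTINEL, converged=False)
    amplitude, cx, cy, sx, sy, background = popt
    resid = win.ravel() - _gauss2d((xs, ys), *popt)
    return SpotFit(center=(float(cx), float(cy)), sigma_x=float(sx), sigma_y=float(sy),
                   amplitude=float(amplitude), background=float(background),
                   residual_rms=float(np.sqrt(np.mean(resid**2))))


# ---------------------------------------------------------------------------
# channel registration (displacement-vote Hough)
# ---------------------------------------------------------------------------

def estimate_channel_transform(
    donor_spots,
    acceptor_spots,
    max_shift: float = 200.0,
    match_radius: float = 2.0,
) -> ChannelTransform:
    """Translation between channels from a displacement-vote accumulator.

    All pairwise displacement vectors (acceptor − donor) are binned into a 2D
    histogram with 1-px bins; the transform is the centroid of the votes in
    the modal bin ± 1 bin. Spot pairs within ``match_radius`` px of the
    transform are reported as matches (greedy nearest-neighbor, unique).
    """
    donor = np.asarray(donor_spots, dtype=float)
    acceptor = np.asarray(acceptor_spots, dtype=float)
    if len(donor) < 3 or len(acceptor) < 3:
        raise AmbiguousRegistrationError("need at least 3 spots per channel")

    disp = (acceptor[None, :, :] - donor[:, None, :]).reshape(-1, 2)
    keep = np.all(np.abs(disp) <= max_shift, axis=1)
    disp = disp[keep]
    if disp.shape[0] == 0:
        raise AmbiguousRegistrationError("no displacement within the search range")

    # 1-px bin voting
    bins_x = np.arange(np.floor(disp[:, 0].min()), np.ceil(disp[:, 0].max()) + 2)
    bins_y = np.arange(np.floor(disp[:, 1].min()), np.ceil(disp[:, 1].max()) + 2)
    hist, bx, by = np.histogram2d(disp[:, 0], disp[:, 1], bins=(bins_x, bins_y))
    i, j = np.unravel_index(np.argmax(hist), hist.shape)
    n_votes = int(hist[i, j])
    if n_votes < 3:
        raise AmbiguousRegistrationError("no modal displacement bin with enough votes")

    # centroid of the votes within the modal bin +- 1 bin
    cx = 0.5 * (bx[i] + bx[i + 1])
    cy = 0.5 * (by[j] + by[j + 1])
    near = np.all(np.abs(disp - [cx, cy]) <= 1.5, axis=1)
    dx, dy = disp[near].mean(axis=0)

    # unique nearest-neighbor matching at the recovered transform
    predicted = donor + [dx, dy]
    d2 = np.sum((predicted[:, None, :] - acceptor[None, :, :]) ** 2, axis=2)
    matches = []
    used_a: set[int] = set()
    order = np.argsort(d2, axis=None)
    for flat in order:
        di, ai = np.unravel_index(flat, d2.shape)
        if d2[di, ai] > match_radius**2:
            break
        if ai in used_a or any(m[0] == di for m in matches):
            continue
        matches.append((int(di), int(ai)))
        used_a.add(int(ai))
    inlier_fraction = len(matches) / min(len(donor), len(acceptor))
    return ChannelTransform(dx=float(dx), dy=float(dy), n_votes=n_votes,
                            inlier_fraction=float(inlier_fraction), matches=matches)


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------

def _fixed_shape_intensity(stack: np.ndarray, x0: float, y0: float,
                           sigma_x: float, sigma_y: float) -> np.ndarray:
    """Per-frame volume of a Gaussian with fixed center/shape (linear A, b solve).

    With the spot shape held fixed (immobilized molecules), each frame needs
    only the amplitude and local background, which solve in closed form.
    """
    xi, yi = int(round(x0)), int(round(y0))
    win = stack[:, yi - _WIN : yi + _WIN + 1, xi - _WIN : xi + _WIN + 1]
    ys, xs = np.mgrid[yi - _WIN : yi + _WIN + 1, xi - _WIN : xi + _WIN + 1]
    g = np.exp(-((xs - x0) ** 2) / (2 * sigma_x**2) - ((ys - y0) ** 2) / (2 * sigma_y**2)).ravel()
    n_px = g.size
    sg, sgg = g.sum(), (g * g).sum()
    flat = win.reshape(win.shape[0], -1)
    sy_, sgy = flat.sum(axis=1), flat @ g
    det = n_px * sgg - sg * sg
    amp = (n_px * sgy - sg * sy_) / det
    return 2 * np.pi * amp * sigma_x * sigma_y


def extract_traces(
    movie_stack: np.ndarray,
    donor_positions: np.ndarray,
    transform: ChannelTransform,
    frame_dt: float = 0.1,
    n_avg_frames: int = 20,
) -> list[IntensityTrace]:
    """Background-subtracted intensity traces at matched spot positions.

    Spot centers and shapes are refined by a full Gaussian fit on the
    ``n_avg_frames``-frame average image and then held fixed; per frame only
    amplitude and background are solved (linear). Molecules whose window
    would clip the frame border are skipped with a logged reason in the
    trace list's place (they are simply excluded).
    """
    stack = np.asarray(movie_stack, dtype=float)
    n_frames, h, w = stack.shape
    avg = stack[: min(n_avg_frames, n_frames)].mean(axis=0)

    traces = []
    for mid, (dx0, dy0) in enumerate(np.asarray(donor_positions, dtype=float)):
        ax0, ay0 = transform.apply([dx0, dy0])
        try:
            dfit = fit_gaussian_2d(avg, (dx0, dy0))
            afit = fit_gaussian_2d(avg, (ax0, ay0))
        except BorderError:
            continue
        ctrs = []
        for fit, (px, py) in ((dfit, (dx0, dy0)), (afit, (ax0, ay0))):
            # fall back to the seed when the refinement did not converge
            ctrs.append(fit if fit.converged else
                        SpotFit((px, py), 1.5, 1.5, 0.0, 0.0, RESIDUAL_SENTINEL, False))
        dfit, afit = ctrs
        try:
            donor = _fixed_shape_intensity(stack, dfit.center[0], dfit.center[1],
                                           dfit.sigma_x, dfit.sigma_y)
            acceptor = _fixed_shape_intensity(stack, afit.center[0], afit.center[1],
                                              afit.sigma_x, afit.sigma_y)
        except (IndexError, ValueError):
            continue
        tr = IntensityTrace(donor=donor, acceptor=acceptor, frame_dt=frame_dt, molecule_id=mid)
        tr.meta["donor_fit"] = dfit
        tr.meta["acceptor_fit"] = afit
        traces.append(tr)
    return traces


def extract_movie(movie: Movie | np.ndarray, min_snr: float = 5.0,
                  frame_dt: float = 0.1) -> tuple[list[IntensityTrace], ChannelTransform]:
    """Full front-end: detect, register and extract traces from a movie stack.

    Detection runs on the 20-frame average of each half-field; the two
    half-fields are registered by displacement voting, and traces are
    extracted at the matched donor positions.
    """
    stack = movie.stack if isinstance(movie, Movie) else np.asarray(movie, dtype=float)
    n_frames, h, w = stack.shape
    half = w // 2
    avg = stack[: min(20, n_frames)].mean(axis=0)

    donor_px = detect_spots(avg[:, :half], min_snr=min_snr)
    accept_px = [(x + half, y) for x, y in detect_spots(avg[:, half:], min_snr=min_snr)]

    donor_fits = []
    for px in donor_px:
        try:
            f = fit_gaussian_2d(avg, px)
        except BorderError:
            continue
        if f.converged:
            donor_fits.append(f.center)
    acceptor_fits = []
    for px in accept_px:
        try:
            f = fit_gaussian_2d(avg, px)
        except BorderError:
            continue
        if f.converged:
            acceptor_fits.append(f.center)

    transform = estimate_channel_transform(donor_fits, acceptor_fits)
    matched_donors = [donor_fits[di] for di, _ in transform.matches]
    traces = extract_traces(stack, np.asarray(matched_donors), transform, frame_dt=frame_dt)
    return traces, transform
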