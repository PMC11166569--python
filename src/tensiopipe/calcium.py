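"""Calcium movie preprocessing, response classification and wave-front speed.

Implements the recipe: per-pixel 5th-percentile baseline removal, spatial
Gaussian low-pass, normalization, threshold-based onset detection, and a
distance-versus-time fit of the expanding wave front over a fixed number of
frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "WaveResult",
    "preprocess",
    "detect_response",
    "wavefront_speed",
    "classify_responder",
    "detect_dye_entry",
]


@dataclass
class WaveResult:
    onset_frame: int
    frames: np.ndarray  # frame indices used for the fit
    radius_um: np.ndarray  # front radius per used frame
    speed_um_s: float
    speed_se: float


def preprocess(
    movie: np.ndarray,
    *,
    gaussian_sigma_px: float = 1.0,
    baseline_percentile: float = 5.0,
    denoise: str | None = None,
    median_size: int = 3,
) -> np.ndarray:
    """Baseline-subtract, low-pass filter and normalize a calcium movie.

    The per-pixel baseline is its 5th-percentile value over time.  An
    optional generic denoiser (``denoise="median"``) stands in for learned
    denoising, which is out of scope.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, y, x)")
    if movie.shape[0] < 20:
        raise ValueError("need >= 20 frames for a stable baseline percentile")
    if denoise == "median":
        movie = ndimage.median_filter(movie, size=(1, median_size, median_size))
    baseline = np.percentile(movie, baseline_percentile, axis=0)
    out = movie - baseline[None]
    if gaussian_sigma_px > 0:
        out = ndimage.gaussian_filter(out, sigma=(0, gaussian_sigma_px, gaussian_sigma_px))
    peak = out.max()
    if peak <= 0:
        warnings.warn("movie is constant after baseline removal", stacklevel=2)
        return np.zeros_like(out)
    return np.clip(out, 0, None) / peak


def detect_response(
    movie_norm: np.ndarray,
    threshold: float = 0.2,
    *,
    min_area_px: int = 5,
) -> tuple[int | None, np.ndarray]:
    """First frame with a super-threshold active region, plus per-frame masks."""
    masks = np.asarray(movie_norm) > threshold
    areas = masks.sum(axis=(1, 2))
    hits = np.flatnonzero(areas >= min_area_px)
    onset = int(hits[0]) if hits.size else None
    return onset, masks


def wavefront_speed(
    movie_norm: np.ndarray,
    origin: tuple[int, int],
    pixel_size_um: float,
    frame_interval_s: float,
    *,
    n_frames: int = 50,
    threshold: float = 0.2,
    min_area_px: int = 5,
    front_percentile: float = 95.0,
) -> WaveResult | None:
    """Wave-front propagation speed from the active-region expansion.

    The front radius in each frame is a high percentile of the distances of
    active pixels from the stimulation origin (robust to speckle); the speed
    is the least-squares slope of radius versus time over ``n_frames``
    starting at onset.  If the front saturates at the cell/frame boundary
    before the window ends, the fit is restricted to pre-saturation frames.
    """
    onset, masks = detect_response(movie_norm, threshold, min_area_px=min_area_px)
    if onset is None:
        return None
    oy, ox = origin
    ny, nx = movie_norm.shape[1:]
    if not (0 <= oy < ny and 0 <= ox < nx):
        raise ValueError("origin outside frame")
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist = np.hypot(yy - oy, xx - ox) * pixel_size_um

    stop = min(onset + n_frames, movie_norm.shape[0])
    frames = []
    radii = []
    for k in range(onset, stop):
        d = dist[masks[k]]
        if d.size < min_area_px:
            continue
        frames.append(k)
        radii.append(np.percentile(d, front_percentile))
    frames = np.asarray(frames)
    radii = np.asarray(radii)
    if frames.size < 3:
        return WaveResult(onset, frames, radii, 0.0, np.nan)

    # saturation guard: drop the trailing plateau where the front has
    # reached the boundary and stopped growing
    r_max = radii.max()
    grown = radii >= 0.98 * r_max
    if grown.sum() > 2:
        first_plateau = int(np.argmax(grown))
        if first_plateau >= 3 and first_plateau < len(radii) - 2:
            warnings.warn(
                "front saturated before the fit window ended; "
                "restricting fit to pre-saturation frames",
                stacklevel=2,
            )
            frames = frames[: first_plateau + 1]
            radii = radii[: first_plateau + 1]

    times = frames * frame_interval_s
    res = stats.linregress(times, radii)
    speed = max(float(res.slope), 0.0)
    return WaveResult(
        onset_frame=onset, frames=frames, radius_um=radii,
        speed_um_s=speed, speed_se=float(res.stderr),
    )


def classify_responder(
    trace: np.ndarray,
    *,
    threshold_fold: float = 3.0,
    n_baseline_frames: int = 20,
) -> tuple[float, bool]:
    """Peak-over-baseline fold change of an ROI trace and responder verdict."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < n_baseline_frames:
        raise ValueError("trace shorter than the baseline window")
    baseline = trace[:n_baseline_frames].mean()
    if baseline <= 0:
        raise ValueError("nonpositive baseline")
    fold = float(trace.max() / baseline)
    return fold, fold >= threshold_fold


def detect_dye_entry(
    red_channel: np.ndarray,
    cell_mask: np.ndarray,
    *,
    n_baseline_frames: int = 20,
    k_sd: float = 5.0,
    sustain_frames: int = 3,
) -> tuple[bool, int | None]:
    """Rupture detection from the membrane-impermeable dye channel.

    A rupture is declared when the in-mask mean intensity exceeds the
    pre-contact mean by more than ``k_sd`` baseline SDs for at least
    ``sustain_frames`` consecutive frames.
    """
    red = np.asarray(red_channel, dtype=float)
    if red.ndim != 3:
        raise ValueError("red channel must be (frames, y, x)")
    series = red[:, cell_mask].mean(axis=1)
    base = series[:n_baseline_frames]
    thresh = base.mean() + k_sd * base.std(ddof=1)
    above = series > thresh
    run = 0
    for i in range(n_baseline_frames, len(series)):
        run = run + 1 if above[i] else 0
        if run >= sustain_frames:
            return True, i - sustain_frames + 1
    return False, None
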