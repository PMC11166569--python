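"""TCSPC lifetime fitting and lifetime-to-membrane-tension conversion.

The decay model is a bi-exponential convolved with the measured instrument
response function plus a flat background, fitted by Poisson maximum
likelihood (correct at the low per-bin counts typical of per-pixel FLIM
histograms).  The larger lifetime component is the tension-relevant one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import MIN_PHOTONS_PER_PIXEL

__all__ = [
    "TCSPCHistogram",
    "LifetimeFit",
    "LifetimeImage",
    "TensionCalibration",
    "fit_reconvolution",
    "fit_lifetime_image",
    "calibrate_tension",
    "lifetime_to_tension",
    "fit_stimulus_tension",
    "integrate_tension_change",
    "analyze_kymograph",
    "KymographResult",
]


@dataclass
class TCSPCHistogram:
    """Time-correlated single-photon-counting histogram with its IRF."""

    time_ns: np.ndarray  # uniform bin centers
    counts: np.ndarray  # photon counts per bin
    irf_counts: np.ndarray  # instrument response, same binning
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.counts = np.asarray(self.counts)
        self.irf_counts = np.asarray(self.irf_counts, dtype=float)
        if not (len(self.time_ns) == len(self.counts) == len(self.irf_counts)):
            raise ValueError("time, counts and IRF must share binning")
        dt = np.diff(self.time_ns)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("bins must be uniform")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])

    @property
    def total_photons(self) -> int:
        return int(np.sum(self.counts))


@dataclass
class LifetimeFit:
    tau_long: float
    tau_short: float
    amp_long: float
    amp_short: float
    background: float
    nll: float  # Poisson negative log-likelihood at the optimum
    se: dict = field(default_factory=dict)
    total_photons: int = 0
    valid: bool = True
    shift_bins: float = 0.0  # fitted sub-bin IRF/data alignment shift


@dataclass
class LifetimeImage:
    """Per-pixel long-lifetime map with a photon-count validity mask."""

    photons: np.ndarray  # (Y, X) photon counts
    tau_long: np.ndarray  # (Y, X), nan where mask is False
    tau_se: np.ndarray  # (Y, X) standard errors, nan where invalid
    mask: np.ndarray  # (Y, X) bool, photons >= threshold and fit succeeded
    pixel_size_um: float
    tau_short: float = np.nan  # image-level fixed short component

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass
class TensionCalibration:
    """Linear lifetime-to-tension conversion: tension = c * lifetime + offset."""

    factor: float  # c, (mN/m) per ns
    factor_sd: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            warnings.warn("calibration slope is not positive", stacklevel=2)


# ---------------------------------------------------------------------------
# reconvolution fitting


def _decay_basis(n: int, dt: float, tau: float) -> np.ndarray:
    return np.exp(-np.arange(n) * dt / tau)


def _shift_kernel(kernel: np.ndarray, shift_bins: float) -> np.ndarray:
    """Fractional-bin shift of the IRF kernel (linear interpolation).

    A free sub-bin shift between IRF and decay absorbs the alignment error
    of binned reconvolution, which otherwise biases the lifetimes.
    """
    if shift_bins == 0.0:
        return kernel
    n = len(kernel)
    x = np.arange(n, dtype=float)
    return np.interp(x - shift_bins, x, kernel, left=0.0, right=0.0)


def _model_counts(
    irf_kernel: np.ndarray, dt: float, taus, amps, background: float,
    shift_bins: float = 0.0,
) -> np.ndarray:
    n = len(irf_kernel)
    kernel = _shift_kernel(irf_kernel, shift_bins)
    m = np.full(n, background, dtype=float)
    for tau, amp in zip(taus, amps):
        m += amp * np.convolve(kernel, _decay_basis(n, dt, tau))[:n]
    return m


def _poisson_nll(counts: np.ndarray, model: np.ndarray) -> float:
    m = np.clip(model, 1e-12, None)
    return float(np.sum(m - counts * np.log(m)))


def _estimate_background(h: TCSPCHistogram) -> float:
    """Mean count in the pre-rise bins (before the IRF carries any weight)."""
    c = np.cumsum(h.irf_counts)
    total = c[-1]
    pre = np.flatnonzero(c < 1e-4 * total) if total > 0 else np.array([], int)
    if pre.size < 3:
        return 0.0
    return float(np.mean(h.counts[pre]))


def _tail_tau_guess(h: TCSPCHistogram, background: float) -> float:
    """Log-linear fit of the decay tail, a cheap lifetime initializer."""
    c = h.counts.astype(float) - background
    peak = int(np.argmax(c))
    start = peak + max(3, (len(c) - peak) // 10)
    sel = np.flatnonzero(c[start:] > 0) + start
    if sel.size < 5:
        return max(h.time_ns[-1] / 5.0, h.bin_width)
    res = stats.linregress(h.time_ns[sel], np.log(c[sel]))
    if res.slope >= 0:
        return max(h.time_ns[-1] / 5.0, h.bin_width)
    return float(-1.0 / res.slope)


def _numerical_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.zeros((n, n))
    steps = rel_step * np.maximum(np.abs(x), 1e-8)
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                4.0 * steps[i] * steps[j]
            )
    # guard against non-finite entries from flat directions
    hess[~np.isfinite(hess)] = 0.0
    del f0
    return hess


def fit_reconvolution(
    h: TCSPCHistogram,
    fix_tau_short: float | None = None,
    *,
    min_photons: int = MIN_PHOTONS_PER_PIXEL,
    single_exponential: bool = False,
    compute_se: bool = True,
    fix_shift: float | None = None,
) -> LifetimeFit:
    """Poisson-MLE reconvolution fit of a (bi-)exponential decay.

    Parameters
    ----------
    h
        Histogram with counts and IRF on a shared uniform time axis.  A
        delta IRF (single nonzero bin) is permitted.
    fix_tau_short
        When given, the short component is frozen at this value and only
        the long lifetime and both amplitudes are free (the per-pixel mode
        of :func:`fit_lifetime_image`).
    min_photons
        Histograms with fewer photons return a masked (``valid=False``)
        result instead of raising.
    """
    total = h.total_photons
    if total < min_photons:
        return LifetimeFit(
            np.nan, np.nan, 0.0, 0.0, 0.0, np.nan, total_photons=total, valid=False
        )
    if np.sum(h.irf_counts) <= 0:
        raise ValueError("IRF histogram is empty")
    kernel = h.irf_counts / np.sum(h.irf_counts)
    dt = h.bin_width
    counts = h.counts.astype(float)
    bg = _estimate_background(h)
    tau0 = _tail_tau_guess(h, bg)
    signal = max(float(np.sum(counts)) - bg * len(counts), 1.0)
    # amplitude scale: photons ~ amp * tau / dt for a normalized kernel
    amp0 = signal * dt / tau0

    def unpack(theta: np.ndarray):
        th = np.clip(theta, -25.0, 25.0)  # keep exp() finite
        if single_exponential:
            taus = [np.exp(th[0])]
            amps = [np.exp(th[1])]
        elif fix_tau_short is not None:
            taus = [np.exp(th[0]), fix_tau_short]
            amps = [np.exp(th[1]), np.exp(th[2])]
        else:
            taus = [np.exp(th[0]), np.exp(th[1])]
            amps = [np.exp(th[2]), np.exp(th[3])]
        shift = fix_shift if fix_shift is not None else theta[-1]
        return taus, amps, shift

    def nll(theta: np.ndarray) -> float:
        taus, amps, shift = unpack(theta)
        return _poisson_nll(
            counts, _model_counts(kernel, dt, taus, amps, bg, shift)
        )

    if single_exponential:
        x0 = np.log([tau0, amp0])
    elif fix_tau_short is not None:
        x0 = np.log([max(tau0, 1.5 * fix_tau_short), 0.7 * amp0, 0.3 * amp0])
    else:
        x0 = np.log([tau0 * 1.3, tau0 / 2.5, 0.6 * amp0, 0.4 * amp0])
    if fix_shift is None:
        x0 = np.append(x0, 0.0)
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000})
    res = optimize.minimize(nll, res.x, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    taus, amps, shift = unpack(res.x)

    if not single_exponential and fix_tau_short is None:
        # order so the larger lifetime is reported as tension-relevant
        order = np.argsort(taus)[::-1]
        taus = [taus[i] for i in order]
        amps = [amps[i] for i in order]
        amp_total = amps[0] + amps[1]
        vanished = amp_total > 0 and min(amps) / amp_total < 1e-3
        if taus[0] / taus[1] < 1.2 or vanished:
            warnings.warn(
                "degenerate bi-exponential fit; collapsing to single exponential",
                stacklevel=2,
            )
            return fit_reconvolution(
                h, min_photons=min_photons, single_exponential=True,
                compute_se=compute_se, fix_shift=fix_shift,
            )

    se: dict = {}
    if compute_se:
        hess = _numerical_hessian(nll, res.x)
        try:
            cov_log = np.linalg.inv(hess)
            diag = np.clip(np.diag(cov_log), 0.0, None)
            se_log = np.sqrt(diag)
        except np.linalg.LinAlgError:
            se_log = np.full(len(res.x), np.nan)
        # delta method back from log-parameters
        if single_exponential:
            se = {"tau_long": taus[0] * se_log[0]}
        elif fix_tau_short is not None:
            se = {"tau_long": taus[0] * se_log[0]}
        else:
            se = {"tau_long": taus[0] * se_log[0], "tau_short": taus[1] * se_log[1]}

    if single_exponential:
        return LifetimeFit(
            tau_long=taus[0], tau_short=taus[0], amp_long=amps[0], amp_short=0.0,
            background=bg, nll=float(res.fun), se=se, total_photons=total,
            shift_bins=float(shift),
        )
    return LifetimeFit(
        tau_long=taus[0],
        tau_short=taus[1] if fix_tau_short is None else fix_tau_short,
        amp_long=amps[0], amp_short=amps[1], background=bg, nll=float(res.fun),
        se=se, total_photons=total, shift_bins=float(shift),
    )


def fit_lifetime_image(
    stack: np.ndarray,
    time_ns: np.ndarray,
    irf_counts: np.ndarray,
    *,
    pixel_size_um: float = 0.1,
    photon_threshold: int = MIN_PHOTONS_PER_PIXEL,
) -> LifetimeImage:
    """Two-stage per-pixel lifetime fitting.

    Stage 1 fits the pooled (image-sum) histogram with both lifetimes free
    and freezes the short component at the image level; stage 2 fits each
    pixel with enough photons with the short lifetime fixed, so only the
    tension-relevant long component varies across the image.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (Y, X, n_bins)")
    ny, nx, _ = stack.shape
    pooled = TCSPCHistogram(time_ns, stack.sum(axis=(0, 1)), irf_counts)
    pooled_fit = fit_reconvolution(pooled, min_photons=photon_threshold)
    if not pooled_fit.valid:
        raise ValueError("pooled histogram has too few photons")
    tau_short = pooled_fit.tau_short
    shift = pooled_fit.shift_bins

    photons = stack.sum(axis=2)
    tau_map = np.full((ny, nx), np.nan)
    se_map = np.full((ny, nx), np.nan)
    mask = photons >= photon_threshold
    if not mask.any():
        raise ValueError("no pixel reaches the photon threshold")
    for y, x in zip(*np.nonzero(mask)):
        h = TCSPCHistogram(time_ns, stack[y, x], irf_counts)
        fit = fit_reconvolution(
            h, fix_tau_short=tau_short, min_photons=photon_threshold,
            fix_shift=shift,
        )
        if fit.valid and np.isfinite(fit.tau_long):
            tau_map[y, x] = fit.tau_long
            se_map[y, x] = fit.se.get("tau_long", np.nan)
        else:
            mask[y, x] = False
    return LifetimeImage(
        photons=photons, tau_long=tau_map, tau_se=se_map, mask=mask,
        pixel_size_um=pixel_size_um, tau_short=tau_short,
    )


# ---------------------------------------------------------------------------
# tension conversion


def calibrate_tension(lifetimes_ns, tensions_mn_per_m) -> TensionCalibration:
    """Least-squares line of tension on lifetime across paired conditions."""
    tau = np.asarray(lifetimes_ns, dtype=float)
    ten = np.asarray(tensions_mn_per_m, dtype=float)
    if tau.shape != ten.shape or tau.size < 3:
        raise ValueError("need at least 3 paired (lifetime, tension) conditions")
    res = stats.linregress(tau, ten)
    return TensionCalibration(
        factor=float(res.slope),
        factor_sd=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def lifetime_to_tension(delta_tau_ns, cal: TensionCalibration):
    """Convert a lifetime change to a membrane tension change: dT = c * dtau."""
    return cal.factor * np.asarray(delta_tau_ns, dtype=float)


def fit_stimulus_tension(stimuli, delta_T) -> tuple[float, float, float]:
    """Slope of mean tension change versus stimulus; returns (alpha, SE, R^2)."""
    x = np.asarray(stimuli, dtype=float)
    y = np.asarray(delta_T, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 stimulus steps")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr), float(res.rvalue**2)


def integrate_tension_change(
    before: LifetimeImage,
    after: LifetimeImage,
    cal: TensionCalibration,
    *,
    k_sigma: float = 2.0,
    noise_sd: float | None = None,
) -> tuple[float, np.ndarray]:
    """Area-integrated tension change over significantly affected pixels.

    A pixel is affected when its lifetime increase exceeds ``k_sigma`` times
    the per-pixel noise SD.  When ``noise_sd`` is not supplied, it is taken
    from the fitted per-pixel standard errors (photon-statistics route) or,
    failing that, from a robust MAD estimate of the lifetime-difference map.
    Returns (sum over affected pixels of c * dtau * pixel_area, mask).
    """
    if before.tau_long.shape != after.tau_long.shape:
        raise ValueError("before/after images are misaligned")
    joint = before.mask & after.mask
    dtau = np.where(joint, after.tau_long - before.tau_long, np.nan)
    if noise_sd is None:
        se = np.sqrt(
            np.nan_to_num(before.tau_se, nan=0.0) ** 2
            + np.nan_to_num(after.tau_se, nan=0.0) ** 2
        )
        if np.any(se[joint] > 0):
            noise = np.where(joint, se, np.inf)
        else:
            vals = dtau[joint]
            mad = np.median(np.abs(vals - np.median(vals)))
            noise = np.full_like(dtau, 1.4826 * mad)
    else:
        noise = np.full_like(dtau, float(noise_sd))
    affected = joint & (dtau > k_sigma * noise)
    total = float(np.nansum(dtau[affected]) * cal.factor * before.pixel_area_um2)
    return total, affected


# ---------------------------------------------------------------------------
# kymograph analysis


@dataclass
class KymographResult:
    """Per-ROI time series with a pre/post-contact step-change verdict."""

    times_s: np.ndarray
    roi_tau_mean: dict
    roi_tau_sd: dict
    roi_intensity_mean: dict
    changed: dict  # roi name -> bool
    change_line: dict  # roi name -> line index or None


def analyze_kymograph(
    tau_lines: np.ndarray,
    intensity_lines: np.ndarray,
    rois: dict,
    contact_time_s: float,
    line_interval_s: float,
    *,
    k_sd: float = 2.0,
    sustain: int = 2,
) -> KymographResult:
    """ROI statistics of a line-scan lifetime kymograph.

    ``tau_lines`` and ``intensity_lines`` are (n_lines, n_pixels); each ROI
    maps a name to pixel indices (0-based, along the scanned line).  A
    change is declared in an ROI when the ROI mean exceeds the pre-contact
    mean by more than ``k_sd`` pre-contact SDs for ``sustain`` consecutive
    lines after contact.
    """
    tau_lines = np.asarray(tau_lines, dtype=float)
    intensity_lines = np.asarray(intensity_lines, dtype=float)
    n_lines = tau_lines.shape[0]
    times = np.arange(n_lines) * line_interval_s
    contact_line = int(round(contact_time_s / line_interval_s))
    if not (0 < contact_line < n_lines):
        raise ValueError("contact time outside the recorded kymograph")

    tau_mean: dict = {}
    tau_sd: dict = {}
    int_mean: dict = {}
    changed: dict = {}
    change_line: dict = {}
    for name, idx in rois.items():
        series = tau_lines[:, idx].mean(axis=1)
        sd_series = tau_lines[:, idx].std(axis=1)
        tau_mean[name] = series
        tau_sd[name] = sd_series
        int_mean[name] = intensity_lines[:, idx].mean(axis=1)
        pre = series[:contact_line]
        thresh = pre.mean() + k_sd * pre.std(ddof=1)
        above = series >= thresh
        above[:contact_line] = False
        hit = None
        run = 0
        for i in range(contact_line, n_lines):
            run = run + 1 if above[i] else 0
            if run >= sustain:
                hit = i - sustain + 1
                break
        changed[name] = hit is not None
        change_line[name] = hit
    return KymographResult(
        times_s=times, roi_tau_mean=tau_mean, roi_tau_sd=tau_sd,
        roi_intensity_mean=int_mean, changed=changed, change_line=change_line,
    )
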