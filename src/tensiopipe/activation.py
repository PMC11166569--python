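"""Mechanosensitivity activation statistics.

Implements the dose-response analysis of critical aspiration pressures:
empirical cumulative frequencies per indentation force, Boltzmann (sigmoid)
fits with a composite goodness-of-model error, the half-activation pressure
versus force line, per-cell total activation pressures, and the additive
stimulus-to-tension model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CumulativeFrequency",
    "SigmoidFit",
    "PcfCurve",
    "TensionCoefficients",
    "boltzmann",
    "cumulative_frequency",
    "fit_boltzmann",
    "fit_pc50_vs_force",
    "total_activation_pressure",
    "delta_T_tot",
    "responder_fraction",
]

RECORD_COLUMNS = ["cell_id", "treatment", "force_nN", "p_crit_mbar", "censored", "seed"]


def boltzmann(p: np.ndarray, a: float, b: float) -> np.ndarray:
    """Sigmoid activation-probability model 1 / (1 + exp(-(p - a) / b))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(p, dtype=float) - a) / b))


@dataclass
class CumulativeFrequency:
    """Empirical CDF of critical pressures at one indentation force."""

    pressures: np.ndarray  # distinct observed pressures, ascending (mbar)
    cumfreq: np.ndarray  # right-continuous step values k/n, nondecreasing
    n_cells: int
    force_nN: float | None = None

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.cumfreq = np.asarray(self.cumfreq, dtype=float)
        if self.pressures.shape != self.cumfreq.shape:
            raise ValueError("pressures and cumfreq must have equal length")
        if np.any(np.diff(self.pressures) <= 0):
            raise ValueError("pressures must be strictly ascending")
        if np.any(np.diff(self.cumfreq) < 0):
            raise ValueError("cumfreq must be nondecreasing")


@dataclass
class SigmoidFit:
    """Boltzmann fit of a cumulative frequency curve.

    ``a`` is the half-maximum pressure, ``b`` the width.  ``sigma`` is the
    standard deviation of ``a`` from the fit covariance.  ``gom`` is the
    goodness-of-model ratio chi2_lin / chi2_sig + 1 and the composite
    ``error`` equals sigma + a / gom.
    """

    a: float
    b: float
    sigma: float
    chi2_sig: float
    chi2_lin: float
    gom: float = field(init=False)
    error: float = field(init=False)
    n_cells: int = 0

    def __post_init__(self) -> None:
        if self.chi2_sig > 0:
            self.gom = self.chi2_lin / self.chi2_sig + 1.0
            self.error = self.sigma + self.a / self.gom
        else:
            self.gom = np.inf
            self.error = self.sigma

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "sigma": self.sigma,
            "chi2_sig": self.chi2_sig,
            "chi2_lin": self.chi2_lin,
            "GoM": self.gom,
            "error": self.error,
            "n": self.n_cells,
        }


@dataclass
class PcfCurve:
    """Half-activation pressure as a linear function of indentation force."""

    forces: np.ndarray
    pc50: np.ndarray
    errors: np.ndarray  # per-force composite errors, carried for display
    intercept: float
    slope: float
    intercept_sd: float
    slope_sd: float
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"force_nN": self.forces, "pc50_mbar": self.pc50, "error_mbar": self.errors}
        )


@dataclass
class TensionCoefficients:
    """Linear stimulus-to-tension coefficients (mean and area-integrated)."""

    alpha_F: float  # (mN/m) / nN
    alpha_p: float  # (mN/m) / mbar
    alpha_F_A: float = 0.0  # (mN/m)*um^2 / nN
    alpha_p_A: float = 0.0  # (mN/m)*um^2 / mbar

    def __post_init__(self) -> None:
        if min(self.alpha_F, self.alpha_p, self.alpha_F_A, self.alpha_p_A) < 0:
            raise ValueError("tension coefficients must be nonnegative")


def _noncensored(records: pd.DataFrame) -> pd.DataFrame:
    if "censored" in records.columns:
        return records.loc[~records["censored"].astype(bool)]
    return records


def cumulative_frequency(
    records: pd.DataFrame,
    force: float | None = None,
    *,
    include_censored: bool = False,
) -> CumulativeFrequency:
    """Empirical cumulative frequency of critical pressures at one force.

    Parameters
    ----------
    records
        Table with at least ``p_crit_mbar`` (and ``force_nN`` when ``force``
        is given).  Censored records are excluded by default; with
        ``include_censored`` they enlarge the denominator without
        contributing steps (a crude Kaplan-Meier-style variant).
    force
        Select records at this indentation force (exact match).
    """
    sub = records
    if force is not None:
        sub = sub.loc[np.isclose(sub["force_nN"].to_numpy(dtype=float), force)]
    observed = _noncensored(sub)
    if len(observed) == 0:
        raise ValueError("all records are censored or no records at this force")
    if len(observed) < 3:
        raise ValueError("need at least 3 non-censored records")
    n = len(sub) if include_censored else len(observed)
    p = np.sort(observed["p_crit_mbar"].to_numpy(dtype=float))
    distinct, counts = np.unique(p, return_counts=True)
    cum = np.cumsum(counts) / n
    return CumulativeFrequency(distinct, cum, n_cells=n, force_nN=force)


def _init_sigmoid(pressures: np.ndarray, cumfreq: np.ndarray) -> tuple[float, float]:
    """Initial (a, b) from interpolated quantile crossings."""
    a0 = float(np.interp(0.5, cumfreq, pressures))
    p25 = float(np.interp(0.25, cumfreq, pressures))
    p75 = float(np.interp(0.75, cumfreq, pressures))
    # logistic quantile spacing: p75 - p25 = 2 b ln 3
    b0 = max((p75 - p25) / (2.0 * np.log(3.0)), 1e-6)
    return a0, b0


def fit_boltzmann(cdf: CumulativeFrequency) -> SigmoidFit:
    """Fit the Boltzmann sigmoid to a cumulative frequency curve.

    Also fits an ordinary least-squares line to the same points; the two
    residual sums of squares feed the goodness-of-model ratio and the
    composite error of the half-maximum pressure.
    """
    p = cdf.pressures
    y = cdf.cumfreq
    if len(p) < 3:
        raise ValueError("need at least 3 cumulative-frequency points")
    if len(p) == 3:
        # small samples on the 25-mbar protocol grid can collapse to three
        # distinct pressures; a 2-parameter fit is still determined
        warnings.warn(
            "only 3 cumulative-frequency points; sigmoid fit is minimally "
            "determined",
            stacklevel=2,
        )
    if y.min() > 0.5 or y.max() < 0.5:
        warnings.warn(
            "cumulative frequencies do not bracket 0.5; "
            "initialization falls back to the nearest point",
            stacklevel=2,
        )
    a0, b0 = _init_sigmoid(p, y)
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann, p, y, p0=(a0, b0), bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger
        raise RuntimeError(f"sigmoid fit did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    resid = y - boltzmann(p, a, b)
    chi2_sig = float(np.sum(resid**2))
    sigma = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
    # straight-line alternative on the same points
    lin = np.polynomial.polynomial.Polynomial.fit(p, y, 1)
    chi2_lin = float(np.sum((y - lin(p)) ** 2))
    return SigmoidFit(
        a=a, b=b, sigma=sigma, chi2_sig=chi2_sig, chi2_lin=chi2_lin, n_cells=cdf.n_cells
    )


def fit_pc50_vs_force(
    forces: np.ndarray,
    pc50: np.ndarray,
    errors: np.ndarray | None = None,
) -> PcfCurve:
    """Unweighted least-squares line through (force, half-activation pressure).

    Per-force errors are carried for display only, matching the published
    analysis where the line fit is a plain least-squares fit.
    """
    forces = np.asarray(forces, dtype=float)
    pc50 = np.asarray(pc50, dtype=float)
    if len(forces) < 3:
        raise ValueError("need at least 3 forces for the line fit")
    if errors is None:
        errors = np.full_like(forces, np.nan)
    res = stats.linregress(forces, pc50)
    return PcfCurve(
        forces=forces,
        pc50=pc50,
        errors=np.asarray(errors, dtype=float),
        intercept=float(res.intercept),
        slope=float(res.slope),
        intercept_sd=float(res.intercept_stderr),
        slope_sd=float(res.stderr),
        r_squared=float(res.rvalue**2),
    )


def _anchor_below(cdf: CumulativeFrequency) -> CumulativeFrequency:
    """Prepend the empirical-CDF zero one protocol step below the first
    observation.

    When every observed pressure sits above the half-maximum (responses
    clamped to the first protocol steps), the sigmoid has no 0.5 crossing to
    anchor on.  The empirical CDF is genuinely zero below the smallest
    observed pressure, so evaluating it one grid step earlier adds a valid
    point rather than invented data.
    """
    step = float(np.min(np.diff(cdf.pressures))) if len(cdf.pressures) > 1 else 25.0
    p0 = cdf.pressures[0] - step
    return CumulativeFrequency(
        np.concatenate([[p0], cdf.pressures]),
        np.concatenate([[0.0], cdf.cumfreq]),
        n_cells=cdf.n_cells,
        force_nN=cdf.force_nN,
    )


def activation_pipeline(records: pd.DataFrame) -> tuple[PcfCurve, dict[float, SigmoidFit]]:
    """Full pipeline: per-force CDFs -> sigmoid fits -> pc50(F) line."""
    observed = _noncensored(records)
    forces = np.sort(observed["force_nN"].unique())
    fits: dict[float, SigmoidFit] = {}
    for f in forces:
        cdf = cumulative_frequency(records, float(f))
        if cdf.cumfreq[0] > 0.5 or len(cdf.pressures) < 3:
            cdf = _anchor_below(cdf)
        fits[float(f)] = fit_boltzmann(cdf)
    pc50 = np.array([fits[float(f)].a for f in forces])
    errs = np.array([fits[float(f)].error for f in forces])
    return fit_pc50_vs_force(forces, pc50, errs), fits


def total_activation_pressure(
    records: pd.DataFrame, slope: float
) -> tuple[pd.Series, SigmoidFit]:
    """Per-cell total activation pressures and the sigmoid fit of their CDF.

    The indentation force is converted to an equivalent pressure with the
    magnitude of the pc50(F) slope, so each total is the critical aspiration
    pressure plus a positive converted indentation contribution.
    """
    observed = _noncensored(records)
    if len(observed) == 0:
        raise ValueError("no non-censored records")
    totals = observed["p_crit_mbar"].astype(float) + abs(slope) * observed[
        "force_nN"
    ].astype(float)
    totals = totals.rename("total_pressure_mbar")
    p = np.sort(totals.to_numpy())
    distinct, counts = np.unique(p, return_counts=True)
    if len(distinct) < 4:
        # degenerate (e.g. noiseless) totals: no sigmoid to fit
        return totals, None
    cdf = CumulativeFrequency(distinct, np.cumsum(counts) / len(p), n_cells=len(p))
    return totals, fit_boltzmann(cdf)


def delta_T_tot(
    F: float, p: float, coeffs: TensionCoefficients
) -> tuple[float, float]:
    """Additive tension model.

    Returns the mean local tension change ``alpha_F * F + alpha_p * p``
    (mN/m) and the area-integrated change ``alpha_F_A * F + alpha_p_A * p``
    ((mN/m) * um^2).
    """
    if F < 0 or p < 0:
        raise ValueError("force and pressure must be nonnegative")
    dT = coeffs.alpha_F * F + coeffs.alpha_p * p
    dT_area = coeffs.alpha_F_A * F + coeffs.alpha_p_A * p
    return dT, dT_area


def responder_fraction(peak_fold_changes, threshold: float = 3.0) -> float:
    """Fraction of cells whose peak fluorescence fold change reaches threshold."""
    folds = np.asarray(list(peak_fold_changes), dtype=float)
    if folds.size == 0:
        raise ValueError("empty fold-change list")
    return float(np.mean(folds >= threshold))
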