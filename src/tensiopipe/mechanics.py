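"""Cell stiffness from force-indentation curves.

Contact-point detection by baseline thresholding followed by a Hertz-type
fit (spherical tip or cylindrical flat punch) of the post-contact segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ForceCurve", "StiffnessFit", "find_contact_point", "fit_hertz"]


@dataclass
class ForceCurve:
    """Approach segment of a force-spectroscopy curve."""

    position_um: np.ndarray  # piezo position, increasing toward the cell
    force_nN: np.ndarray
    approach_speed_um_s: float = 1.0
    spring_constant_N_m: float = 1.0

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.position_um.shape != self.force_nN.shape:
            raise ValueError("position and force must have equal length")
        if np.any(np.diff(self.position_um) <= 0):
            raise ValueError("approach positions must be strictly increasing")


@dataclass
class StiffnessFit:
    contact_um: float
    E_Pa: float
    geometry: str  # "sphere" or "punch"
    tip_radius_um: float
    residual_nN: float  # RMS force residual over the fitted segment
    se_Pa: float
    nu: float = 0.5


def find_contact_point(
    curve: ForceCurve,
    force_threshold_nN: float | None = None,
    *,
    baseline_fraction: float = 0.3,
    k_sd: float = 3.0,
    refine: bool = True,
) -> float:
    """Contact position where force first exceeds the detrended baseline.

    The baseline tilt is removed with a linear fit over the leading
    ``baseline_fraction`` of the curve; the threshold defaults to ``k_sd``
    baseline-noise SDs.  With ``refine`` the initial crossing is sharpened
    by extrapolating the early post-contact rise back to zero force, which
    removes the systematic late bias of plain thresholding on noisy curves.
    """
    n = len(curve.position_um)
    nb = max(int(baseline_fraction * n), 5)
    if nb < 0.2 * n:
        raise ValueError("baseline segment must cover >= 20% of the curve")
    x, f = curve.position_um, curve.force_nN
    res = stats.linregress(x[:nb], f[:nb])
    detrended = f - (res.intercept + res.slope * x)
    noise_sd = float(detrended[:nb].std(ddof=1))
    thr = force_threshold_nN if force_threshold_nN is not None else k_sd * noise_sd
    thr = max(thr, 1e-12)
    over = detrended > thr
    over[: nb // 2] = False
    # require a sustained crossing so single noise spikes cannot trigger it
    sustained = over & np.roll(over, -1) & np.roll(over, -2)
    sustained[-2:] = over[-2:]
    above = np.flatnonzero(sustained)
    if above.size == 0:
        raise ValueError("no contact: force never exceeds the threshold")
    idx = int(above[0])
    contact = float(x[idx])
    if refine:
        # back-extrapolate the early rise (threshold .. 8x threshold) to zero
        hi = detrended[idx:] <= 8.0 * thr
        stop = idx + (int(np.argmin(hi)) if not hi.all() else len(hi))
        sel = slice(idx, max(stop, idx + 5))
        if sel.stop <= n and sel.stop - sel.start >= 3:
            rise = stats.linregress(x[sel], detrended[sel])
            if rise.slope > 0:
                x0 = -rise.intercept / rise.slope
                if x[0] <= x0 <= contact + (x[1] - x[0]):
                    contact = float(x0)
    return contact


def _hertz_shape(delta: np.ndarray, geometry: str, tip_radius_um: float) -> np.ndarray:
    """Force per unit E/(1-nu^2), in units consistent with nN when E is in Pa.

    With delta and R in um: F[nN] = E[Pa]/(1-nu^2) * g(delta) * 1e-3,
    since Pa * um^2 = 1e-12 N * 1e3 = 1e-3 nN per um^2.
    """
    if geometry == "sphere":
        return (4.0 / 3.0) * np.sqrt(tip_radius_um) * delta**1.5 * 1e-3
    if geometry == "punch":
        return 2.0 * tip_radius_um * delta * 1e-3
    raise ValueError(f"unknown geometry {geometry!r}")


def fit_hertz(
    curve: ForceCurve,
    contact_um: float,
    *,
    geometry: str = "punch",
    tip_radius_um: float = 1.0,
    nu: float = 0.5,
    max_indentation_um: float | None = None,
    refine_contact_um: float = 0.0,
) -> StiffnessFit:
    """Least-squares Hertz-type fit of the post-contact segment.

    The model is linear in the elastic modulus, so for a given contact
    point E has a closed-form least-squares solution; its SE comes from the
    residual variance.  ``refine_contact_um`` > 0 additionally searches for
    the contact point within that window around the initial estimate,
    minimizing the residual sum of squares.
    """

    def solve(contact: float):
        x, f = curve.position_um, curve.force_nN
        delta = x - contact
        sel = delta > 0
        if max_indentation_um is not None:
            sel &= delta <= max_indentation_um
        if sel.sum() < 10:
            raise ValueError("need >= 10 points beyond the contact point")
        d = delta[sel]
        offset = float(np.median(f[~(delta > 0)])) if (~(delta > 0)).any() else 0.0
        y = f[sel] - offset
        g = _hertz_shape(d, geometry, tip_radius_um) / (1.0 - nu**2)
        denom = float(np.dot(g, g))
        E = float(np.dot(g, y) / denom)
        resid = y - E * g
        return E, resid, denom, len(d)

    contact = float(contact_um)
    if refine_contact_um > 0:
        from scipy.optimize import minimize_scalar

        def rss(c: float) -> float:
            try:
                _, resid, _, _ = solve(c)
            except ValueError:
                return np.inf
            return float(np.sum(resid**2))

        res = minimize_scalar(
            rss,
            bounds=(contact - refine_contact_um, contact + refine_contact_um),
            method="bounded",
        )
        if np.isfinite(res.fun):
            contact = float(res.x)

    E, resid, denom, npts = solve(contact)
    if E <= 0:
        raise ValueError("fitted modulus is not positive")
    dof = max(npts - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / denom))
    return StiffnessFit(
        contact_um=contact, E_Pa=E, geometry=geometry,
        tip_radius_um=tip_radius_um,
        residual_nN=float(np.sqrt(np.mean(resid**2))), se_Pa=se, nu=nu,
    )
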