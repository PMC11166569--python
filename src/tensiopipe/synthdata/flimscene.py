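"""Generator for FLIM scenes: per-pixel TCSPC stacks and kymograph lines.

A scene carries a background long lifetime everywhere and an elevated long
lifetime inside an annulus emulating the rim of the 2-um pipette tip, with
the elevation scaled by the active step of a stimulus series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tcspc import TCSPCGenConfig, generate_tcspc_histogram

__all__ = ["FlimSceneConfig", "generate_flim_scene", "generate_flim_kymograph"]


@dataclass
class FlimSceneConfig:
    shape: tuple = (16, 16)  # (y, x) pixels
    pixel_size_um: float = 0.1
    tau_base: float = 4.0  # background long lifetime (ns)
    tau_short: float = 1.5  # shared short component (ns)
    frac_long: float = 0.6
    tau_site_delta: float = 0.2  # lifetime elevation per unit stimulus scale
    site_center: tuple = (8, 8)  # pixels
    site_radius_um: float = 1.0  # annulus mid-radius
    site_width_um: float = 0.3  # annulus full width
    photons_per_pixel: int = 2000
    irf_fwhm: float = 0.2
    window_ns: float = 25.0
    n_bins: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")
        if self.shape[0] == 1:
            return  # line-scan (kymograph) mode: no 2D site annulus
        cy, cx = self.site_center
        ny, nx = self.shape
        r_out = (self.site_radius_um + self.site_width_um / 2) / self.pixel_size_um
        if (
            cy - r_out < 0 or cy + r_out >= ny or cx - r_out < 0 or cx + r_out >= nx
        ):
            raise ValueError("site annulus must lie inside the frame")


def site_mask(cfg: FlimSceneConfig) -> np.ndarray:
    ny, nx = cfg.shape
    cy, cx = cfg.site_center
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx) * cfg.pixel_size_um
    return np.abs(r - cfg.site_radius_um) <= cfg.site_width_um / 2


def _pixel_histogram(cfg: FlimSceneConfig, tau_long: float, seed: int) -> np.ndarray:
    sub = TCSPCGenConfig(
        tau_long=tau_long,
        tau_short=cfg.tau_short,
        frac_long=cfg.frac_long,
        irf_fwhm=cfg.irf_fwhm,
        n_photons=cfg.photons_per_pixel,
        window_ns=cfg.window_ns,
        n_bins=cfg.n_bins,
        seed=seed,
    )
    return generate_tcspc_histogram(sub)


def generate_flim_scene(
    cfg: FlimSceneConfig, stimulus_scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel TCSPC stack for one stimulus step.

    Returns (stack (y, x, n_bins), time_ns, irf_counts, truth tau_long map).
    ``stimulus_scale`` multiplies the site lifetime elevation, so a stimulus
    series maps to a sequence of scenes with growing site contrast.
    """
    mask = site_mask(cfg)
    ny, nx = cfg.shape
    tau_map = np.full((ny, nx), cfg.tau_base)
    tau_map[mask] += cfg.tau_site_delta * stimulus_scale
    stack = np.zeros((ny, nx, cfg.n_bins), dtype=np.int64)
    time_ns = irf = None
    base = np.random.SeedSequence(cfg.seed).generate_state(1)[0]
    for y in range(ny):
        for x in range(nx):
            h = _pixel_histogram(cfg, tau_map[y, x], int(base) + y * nx + x)
            stack[y, x] = h.counts
            if time_ns is None:
                time_ns, irf = h.time_ns, h.irf_counts
    return stack, time_ns, irf, tau_map


def generate_flim_kymograph(
    cfg: FlimSceneConfig,
    n_lines: int,
    contact_line: int,
    *,
    site_pixels: slice,
    membrane_pixels: slice,
    delta_site: float = 0.2,
    delta_membrane: float = 0.0,
    tau_noise_sd: float = 0.02,
    intensity_step: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Line-scan lifetime/intensity kymograph with programmed step changes.

    After ``contact_line`` the site ROI lifetime steps by ``delta_site`` and
    the outer-membrane ROI by ``delta_membrane`` (0 emulates an intact cell,
    > 0 a cytoskeleton-free bleb).  Returns (tau_lines, intensity_lines),
    each (n_lines, n_pixels).
    """
    rng = np.random.default_rng(cfg.seed)
    n_pix = cfg.shape[-1]
    tau = np.full((n_lines, n_pix), cfg.tau_base)
    intensity = np.ones((n_lines, n_pix))
    tau[contact_line:, site_pixels] += delta_site
    tau[contact_line:, membrane_pixels] += delta_membrane
    intensity[contact_line:, site_pixels] += intensity_step
    tau += rng.normal(0.0, tau_noise_sd, size=tau.shape)
    intensity += rng.normal(0.0, 0.02, size=intensity.shape)
    return tau, intensity
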