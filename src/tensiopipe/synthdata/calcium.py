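"""Generator for synthetic calcium-response movies.

Responder movies show intensity stepping up behind a circular front that
expands from the stimulation site at a programmed speed; rupture movies
additionally ramp a red (membrane-impermeable dye) channel inside the cell
mask after the rupture frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import DEFAULT_WAVE_SPEED_UM_S

__all__ = ["CalciumMovieConfig", "generate_calcium_movie"]


@dataclass
class CalciumMovieConfig:
    shape: tuple = (120, 120, 120)  # (frames, y, x)
    pixel_size_um: float = 0.5
    frame_interval_s: float = 0.05
    origin: tuple = (60, 60)  # stimulation-site pixel (y, x)
    wave_speed_um_s: float = DEFAULT_WAVE_SPEED_UM_S
    onset_frame: int = 20
    baseline_level: float = 100.0
    response_fold: float = 4.0
    noise_sd: float = 0.0
    front_width_um: float = 0.0  # optional Gaussian rise width of the front
    responder: bool = True
    rupture: bool = False
    rupture_frame: int | None = None
    cell_radius_um: float | None = None  # None: cell fills the frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wave_speed_um_s < 0:
            raise ValueError("wave_speed must be >= 0")
        if self.response_fold < 1:
            raise ValueError("response_fold must be >= 1")
        oy, ox = self.origin
        _, ny, nx = self.shape
        if not (0 <= oy < ny and 0 <= ox < nx):
            raise ValueError("origin outside frame")


def generate_calcium_movie(
    cfg: CalciumMovieConfig,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (green movie, red movie or None), both (frames, y, x) float."""
    rng = np.random.default_rng(cfg.seed)
    nf, ny, nx = cfg.shape
    oy, ox = cfg.origin
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist = np.hypot(yy - oy, xx - ox) * cfg.pixel_size_um
    cell = (
        dist <= cfg.cell_radius_um
        if cfg.cell_radius_um is not None
        else np.ones((ny, nx), dtype=bool)
    )

    green = np.full((nf, ny, nx), cfg.baseline_level, dtype=float)
    if cfg.responder and cfg.wave_speed_um_s >= 0:
        amp = cfg.baseline_level * (cfg.response_fold - 1.0)
        for k in range(cfg.onset_frame, nf):
            radius = cfg.wave_speed_um_s * (k - cfg.onset_frame) * cfg.frame_interval_s
            if cfg.front_width_um > 0:
                rise = 0.5 * (1.0 - np.tanh((dist - radius) / cfg.front_width_um))
            else:
                rise = (dist <= radius).astype(float)
            green[k] += amp * rise * cell

    red = None
    if cfg.rupture:
        rf = cfg.rupture_frame if cfg.rupture_frame is not None else cfg.onset_frame
        red = np.zeros((nf, ny, nx), dtype=float)
        for k in range(rf, nf):
            # dye fills the cell over ~10 frames after rupture
            level = cfg.baseline_level * min((k - rf + 1) / 10.0, 1.0)
            red[k] = level * cell

    if cfg.noise_sd > 0:
        green = green + rng.normal(0.0, cfg.noise_sd, size=green.shape)
        if red is not None:
            red = red + rng.normal(0.0, cfg.noise_sd, size=red.shape)
    return green, red
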