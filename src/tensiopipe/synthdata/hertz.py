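"""Generator for Hertz-type force-indentation approach curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..mechanics import ForceCurve

__all__ = ["HertzGenConfig", "generate_force_curve", "hertz_force"]


@dataclass
class HertzGenConfig:
    E_true_Pa: float = 1000.0
    nu: float = 0.5
    geometry: str = "sphere"  # "sphere" or "punch"
    tip_radius_um: float = 1.0  # sphere radius or flat-punch radius
    contact_offset_um: float = 1.0
    max_indentation_um: float = 1.0
    noise_sd_nN: float = 0.0
    n_points: int = 500
    approach_speed_um_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true_Pa <= 0:
            raise ValueError("E_true must be positive")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")
        if self.max_indentation_um <= 0:
            raise ValueError("max_indentation must be positive")
        if self.geometry not in ("sphere", "punch"):
            raise ValueError("geometry must be 'sphere' or 'punch'")


def hertz_force(
    delta_um: np.ndarray, E_Pa: float, nu: float, geometry: str, tip_radius_um: float
) -> np.ndarray:
    """Contact force in nN for indentation depth in um.

    Sphere: F = (4/3) E/(1-nu^2) sqrt(R) delta^{3/2};
    flat punch: F = 2 E/(1-nu^2) a delta.  Pa * um^2 = 1e-3 nN.
    """
    delta = np.clip(np.asarray(delta_um, dtype=float), 0.0, None)
    pref = E_Pa / (1.0 - nu**2) * 1e-3
    if geometry == "sphere":
        return (4.0 / 3.0) * pref * np.sqrt(tip_radius_um) * delta**1.5
    return 2.0 * pref * tip_radius_um * delta


def generate_force_curve(cfg: HertzGenConfig) -> ForceCurve:
    rng = np.random.default_rng(cfg.seed)
    z = np.linspace(
        0.0, cfg.contact_offset_um + cfg.max_indentation_um, cfg.n_points
    )
    force = hertz_force(
        z - cfg.contact_offset_um, cfg.E_true_Pa, cfg.nu, cfg.geometry,
        cfg.tip_radius_um,
    )
    if cfg.noise_sd_nN > 0:
        force = force + rng.normal(0.0, cfg.noise_sd_nN, size=force.shape)
    return ForceCurve(
        position_um=z, force_nN=force, approach_speed_um_s=cfg.approach_speed_um_s
    )
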