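"""Generator for per-cell critical aspiration pressure records.

Latent activation thresholds follow a logistic (Boltzmann) law centred on a
linear half-activation line a0 + beta * F; observed pressures are the first
step of the 25-mbar aspiration protocol at or above the latent threshold,
and cells whose threshold exceeds the protocol maximum are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..constants import DEFAULT_PRESSURE_MAX_MBAR, DEFAULT_PRESSURE_STEP_MBAR

__all__ = ["ActivationGenConfig", "generate_critical_pressures"]


@dataclass
class ActivationGenConfig:
    forces: tuple  # indentation forces (nN)
    n_per_force: int | tuple  # cells per force (scalar or per-force)
    intercept_a0: float  # half-activation pressure at F = 0 (mbar)
    slope_beta: float  # d pC50 / dF (mbar/nN), negative for softer response
    width_b: float  # Boltzmann width (mbar); 0 = deterministic limit
    pressure_step: float = DEFAULT_PRESSURE_STEP_MBAR
    p_max: float = DEFAULT_PRESSURE_MAX_MBAR
    treatment: str = "ctrl"
    seed: int = 0
    n_list: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.forces = tuple(float(f) for f in self.forces)
        if any(f <= 0 for f in self.forces):
            raise ValueError("forces must be positive")
        if np.isscalar(self.n_per_force):
            self.n_list = tuple(int(self.n_per_force) for _ in self.forces)
        else:
            self.n_list = tuple(int(n) for n in self.n_per_force)
        if len(self.n_list) != len(self.forces):
            raise ValueError("n_per_force must match forces")
        if any(n < 1 for n in self.n_list):
            raise ValueError("n_per_force must be >= 1")
        if self.width_b < 0 or self.pressure_step < 0:
            raise ValueError("width_b and pressure_step must be nonnegative")
        if self.intercept_a0 + self.slope_beta * max(self.forces) <= 0:
            raise ValueError(
                "configuration implies nonpositive mean activation pressure "
                "at the largest force"
            )


def generate_critical_pressures(cfg: ActivationGenConfig) -> pd.DataFrame:
    """Draw per-cell critical pressures on the stepped-aspiration protocol.

    For each force F, latent thresholds are a0 + beta*F + b*ln(u/(1-u)) with
    u ~ U(0,1) (logistic quantile function), snapped UP to the next protocol
    step (the first pressure actually reached during stepping).  Draws above
    ``p_max`` are retained but flagged censored.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    cell = 0
    for force, n in zip(cfg.forces, cfg.n_list):
        center = cfg.intercept_a0 + cfg.slope_beta * force
        u = rng.uniform(size=n)
        p_raw = center + cfg.width_b * np.log(u / (1.0 - u))
        if cfg.pressure_step > 0:
            p_obs = np.ceil(p_raw / cfg.pressure_step) * cfg.pressure_step
            p_obs = np.maximum(p_obs, cfg.pressure_step)
        else:
            p_obs = np.maximum(p_raw, np.finfo(float).tiny)
        censored = p_raw > cfg.p_max
        for p, c in zip(p_obs, censored):
            rows.append(
                {
                    "cell_id": f"{cfg.treatment}_{cell:05d}",
                    "treatment": cfg.treatment,
                    "force_nN": force,
                    "p_crit_mbar": float(min(p, cfg.p_max)) if not c else float(p),
                    "censored": bool(c),
                    "seed": cfg.seed,
                }
            )
            cell += 1
    return pd.DataFrame(rows)
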