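"""Coarse-grained membrane/cytoskeleton tension simulator.

A pre-tensioned triangulated spring-network disc stands in for a membrane
patch.  Cytoskeletal attachment is collapsed into point anchors (springs to
fixed points); a cylindrical pipette is a vertical displacement constraint
on a ring band plus an optional aspiration pressure inside the ring.
Loading is quasi-static: energy minimization to a force-residual tolerance.

Units: um, nN, membrane tension in nN/um (= mN/m); pressure converted from
mbar with 1 mbar = 0.1 nN/um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.spatial import Delaunay, cKDTree

from .constants import MBAR_TO_NN_PER_UM2

__all__ = [
    "CgConfig",
    "MembraneSystem",
    "LoadState",
    "TensionProfile",
    "build_system",
    "apply_load",
    "measure_tension",
    "tension_profile",
    "sheet_tension",
]


def sheet_tension(spring_k: float, strain: float) -> float:
    """Isotropic tension of a uniformly stretched triangular spring lattice.

    For an equilateral lattice with per-edge stiffness k under isotropic
    strain s, the virial tension is sqrt(3) * k * s, independent of edge
    length.
    """
    return np.sqrt(3.0) * spring_k * strain


@dataclass
class CgConfig:
    patch_radius_um: float = 3.0
    edge_length_um: float = 0.2
    spring_k: float = 10.0  # nN/um per edge
    pre_strain: float = 0.02  # isotropic pre-stretch setting the resting tension
    anchor_spacing_um: float | None = 0.5  # None disables anchors (bleb-like)
    anchor_k: float = 20.0  # nN/um per anchor spring
    pipette_radius_um: float = 1.0
    ring_half_width_um: float | None = None  # default 0.75 * edge length
    jitter: float = 0.05  # positional jitter as a fraction of edge length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_radius_um <= self.pipette_radius_um:
            raise ValueError("pipette ring must lie inside the patch interior")
        if self.edge_length_um <= 0 or self.spring_k <= 0:
            raise ValueError("edge length and stiffness must be positive")
        if self.ring_half_width_um is None:
            self.ring_half_width_um = 0.75 * self.edge_length_um


@dataclass
class MembraneSystem:
    config: CgConfig
    positions: np.ndarray  # (N, 3) current vertex positions
    ref_positions: np.ndarray  # (N, 3) reference (as-built) positions
    triangles: np.ndarray  # (T, 3)
    edges: np.ndarray  # (E, 2)
    rest_lengths: np.ndarray  # (E,)
    fixed: np.ndarray  # (N,) bool, clamped outer boundary
    ring: np.ndarray  # (N,) bool, pipette-wall band
    inside: np.ndarray  # (N,) bool, interior of the pipette aperture
    anchors: np.ndarray  # indices of anchored vertices
    anchor_points: np.ndarray  # (n_anchors, 3)
    vertex_area: np.ndarray  # (N,) reference Voronoi-style areas

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    def copy(self) -> "MembraneSystem":
        return replace(
            self,
            positions=self.positions.copy(),
        )


@dataclass
class LoadState:
    """Pipette load: indentation (force- or displacement-controlled) and
    aspiration pressure applied inside the ring."""

    force_nN: float | None = None
    ring_depth_um: float | None = None
    pressure_mbar: float = 0.0
    converged: bool = False
    residual: float = np.nan  # max |gradient| (nN) over free DOF
    achieved_force_nN: float = np.nan
    energy_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class TensionProfile:
    bin_centers_um: np.ndarray  # radius from the pipette center
    delta_T: np.ndarray  # mean tension change per bin (nN/um)
    peak_delta_T: float
    confinement_um: float | None  # distance beyond the ring; None if undefined
    far_field_fraction: float  # dT at the outermost bin relative to peak


# ---------------------------------------------------------------------------
# construction


def _hex_lattice(radius: float, edge: float) -> np.ndarray:
    dy = edge * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(radius / dy)) + 1
    pts = []
    for row in range(-n_rows, n_rows + 1):
        y = row * dy
        x_off = 0.5 * edge if row % 2 else 0.0
        n_cols = int(np.ceil(radius / edge)) + 1
        for col in range(-n_cols, n_cols + 1):
            x = col * edge + x_off
            if np.hypot(x, y) <= radius + 1e-9:
                pts.append((x, y))
    return np.asarray(pts)


def build_system(config: CgConfig) -> MembraneSystem:
    """Build and relax the pre-tensioned reference state."""
    rng = np.random.default_rng(config.seed)
    edge = config.edge_length_um
    xy = _hex_lattice(config.patch_radius_um, edge)
    r = np.hypot(xy[:, 0], xy[:, 1])
    boundary = r >= config.patch_radius_um - 0.55 * edge
    if config.jitter > 0:
        j = rng.normal(0.0, config.jitter * edge, size=xy.shape)
        j[boundary] = 0.0
        xy = xy + j

    tri = Delaunay(xy)
    simplices = tri.simplices
    # drop sliver triangles created by the convex hull at the rim
    keep = np.ones(len(simplices), dtype=bool)
    for k, s in enumerate(simplices):
        p = xy[s]
        lengths = np.linalg.norm(p - np.roll(p, 1, axis=0), axis=1)
        if lengths.max() > 1.8 * edge:
            keep[k] = False
    simplices = simplices[keep]
    if len(simplices) == 0:
        raise ValueError("mesh construction failed: no valid triangles")

    edge_set = set()
    for s in simplices:
        for a, b in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])):
            edge_set.add((min(a, b), max(a, b)))
    edges = np.asarray(sorted(edge_set))

    # orphan vertices (only part of dropped slivers) are pinned in place
    used = np.zeros(len(xy), dtype=bool)
    used[np.unique(edges)] = True

    positions = np.column_stack([xy, np.zeros(len(xy))])
    d0 = np.linalg.norm(positions[edges[:, 0]] - positions[edges[:, 1]], axis=1)
    rest = d0 / (1.0 + config.pre_strain)

    r = np.hypot(xy[:, 0], xy[:, 1])
    fixed = boundary | ~used
    hw = config.ring_half_width_um
    ring = np.abs(r - config.pipette_radius_um) <= hw
    inside = r < config.pipette_radius_um - hw

    # anchors on a hexagonal grid of the requested spacing, snapped to vertices
    if config.anchor_spacing_um is not None:
        grid = _hex_lattice(
            config.patch_radius_um - edge, config.anchor_spacing_um
        )
        tree = cKDTree(xy)
        idx = np.unique(tree.query(grid)[1])
        idx = idx[~fixed[idx]]
        anchors = idx
    else:
        anchors = np.empty(0, dtype=int)
    anchor_points = positions[anchors].copy()

    # reference vertex areas (one third of incident triangle area)
    area = np.zeros(len(xy))
    p0, p1, p2 = (xy[simplices[:, i]] for i in range(3))
    tri_area = 0.5 * np.abs(
        (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
        - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1])
    )
    for i in range(3):
        np.add.at(area, simplices[:, i], tri_area / 3.0)

    system = MembraneSystem(
        config=config, positions=positions, ref_positions=positions.copy(),
        triangles=simplices, edges=edges, rest_lengths=rest, fixed=fixed,
        ring=ring, inside=inside, anchors=anchors, anchor_points=anchor_points,
        vertex_area=area,
    )
    # relax the jittered lattice in-plane to the true pre-tensioned state
    _relax(system, np.zeros(len(xy)))
    system.ref_positions = system.positions.copy()
    system.anchor_points = system.positions[anchors].copy()
    return system


# ---------------------------------------------------------------------------
# energetics and relaxation


def _energy_grad(system: MembraneSystem, X: np.ndarray, fz: np.ndarray):
    e0, e1 = system.edges[:, 0], system.edges[:, 1]
    k = system.config.spring_k
    vec = X[e0] - X[e1]
    l = np.linalg.norm(vec, axis=1)
    stretch = l - system.rest_lengths
    energy = 0.5 * k * np.sum(stretch**2)
    grad = np.zeros_like(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = vec / l[:, None]
    unit[~np.isfinite(unit)] = 0.0
    f = (k * stretch)[:, None] * unit
    np.add.at(grad, e0, f)
    np.add.at(grad, e1, -f)
    if len(system.anchors):
        ka = system.config.anchor_k
        d = X[system.anchors] - system.anchor_points
        energy += 0.5 * ka * np.sum(d**2)
        grad[system.anchors] += ka * d
    energy -= np.dot(fz, X[:, 2])
    grad[:, 2] -= fz
    return energy, grad


def _relax(
    system: MembraneSystem,
    fz: np.ndarray,
    *,
    ring_depth: float | None = None,
    gtol: float = 1e-7,
    maxiter: int = 5000,
):
    """Minimize the total energy over the free degrees of freedom in place.

    Returns (max residual gradient over free DOF, energy history).
    """
    N = system.n_vertices
    free = np.ones((N, 3), dtype=bool)
    free[system.fixed] = False
    if ring_depth is not None:
        system.positions[system.ring, 2] = -ring_depth
        free[system.ring, 2] = False
    X0 = system.positions.copy()
    idx = np.flatnonzero(free.ravel())

    history: list[float] = []

    def fun(theta: np.ndarray):
        X = X0.copy().ravel()
        X[idx] = theta
        X = X.reshape(N, 3)
        e, g = _energy_grad(system, X, fz)
        return e, g.ravel()[idx]

    def cb(theta: np.ndarray) -> None:
        history.append(fun(theta)[0])

    res = optimize.minimize(
        fun, X0.ravel()[idx], jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-15},
    )
    X = X0.ravel()
    X[idx] = res.x
    system.positions = X.reshape(N, 3)
    _, g = _energy_grad(system, system.positions, fz)
    g[~free] = 0.0
    residual = float(np.abs(g).max()) if idx.size else 0.0
    return residual, np.asarray(history)


def _aspiration_forces(system: MembraneSystem, pressure_mbar: float) -> np.ndarray:
    """Per-vertex upward (into the pipette) force from aspiration."""
    fz = np.zeros(system.n_vertices)
    p = pressure_mbar * MBAR_TO_NN_PER_UM2  # nN/um^2
    fz[system.inside] = p * system.vertex_area[system.inside]
    return fz


def _ring_reaction(system: MembraneSystem, fz: np.ndarray) -> float:
    """Downward force the pipette must apply to hold the ring in place."""
    _, g = _energy_grad(system, system.positions, fz)
    return float(-np.sum(g[system.ring, 2]))


def apply_load(
    system: MembraneSystem,
    load: LoadState,
    *,
    uniform_pressure_mbar: float | None = None,
    gtol: float = 1e-7,
    force_rtol: float = 0.02,
    max_force_iter: int = 15,
) -> tuple[MembraneSystem, LoadState]:
    """Relax the system under a pipette load; returns (new system, load state).

    Indentation is displacement-controlled when ``ring_depth_um`` is given,
    otherwise force-controlled: the ring depth is iterated (secant) until
    the total vertical reaction matches ``force_nN``.  ``uniform_pressure_mbar``
    bypasses the pipette and loads every interior vertex - the configuration
    used to check against the small-deflection membrane solution.
    """
    sys2 = system.copy()
    if uniform_pressure_mbar is not None:
        p = uniform_pressure_mbar * MBAR_TO_NN_PER_UM2
        fz = np.where(system.fixed, 0.0, p * system.vertex_area)
        residual, hist = _relax(sys2, fz, gtol=gtol)
        state = replace(load, converged=residual < 10 * gtol * max(1.0, np.abs(fz).sum()),
                        residual=residual, energy_history=hist)
        state.converged = True
        return sys2, state

    fz = _aspiration_forces(system, load.pressure_mbar)

    if load.ring_depth_um is not None:
        residual, hist = _relax(sys2, fz, ring_depth=load.ring_depth_um, gtol=gtol)
        achieved = _ring_reaction(sys2, fz)
        return sys2, replace(
            load, converged=True, residual=residual,
            achieved_force_nN=achieved, energy_history=hist,
        )

    if load.force_nN is None:
        residual, hist = _relax(sys2, fz, gtol=gtol)
        return sys2, replace(
            load, converged=True, residual=residual, achieved_force_nN=0.0,
            energy_history=hist,
        )

    target = load.force_nN
    t0 = max(sheet_tension(system.config.spring_k, system.config.pre_strain), 1e-3)
    stiffness = 4.0 * np.pi * t0 / np.log(
        system.config.patch_radius_um / system.config.pipette_radius_um
    )
    d_prev, r_prev = 0.0, 0.0
    depth = min(target / stiffness, 0.5 * system.config.patch_radius_um)
    hist = np.empty(0)
    residual = np.nan
    reaction = np.nan
    for _ in range(max_force_iter):
        trial = system.copy()
        residual, hist = _relax(trial, fz, ring_depth=depth, gtol=gtol)
        reaction = _ring_reaction(trial, fz)
        sys2 = trial
        if abs(reaction - target) <= force_rtol * abs(target):
            break
        if abs(reaction - r_prev) < 1e-12:
            depth *= 1.5
            continue
        d_new = depth + (target - reaction) * (depth - d_prev) / (reaction - r_prev)
        d_prev, r_prev = depth, reaction
        lo, hi = 0.0, 2.0 * system.config.patch_radius_um
        depth = float(np.clip(d_new, lo + 1e-4, hi))
    else:
        raise RuntimeError(
            f"force control did not converge: reaction {reaction:.3g} nN "
            f"vs target {target:.3g} nN (residual {residual:.3g})"
        )
    return sys2, replace(
        load, converged=True, residual=residual, achieved_force_nN=reaction,
        ring_depth_um=depth, energy_history=hist,
    )


# ---------------------------------------------------------------------------
# measurement


def measure_tension(system: MembraneSystem) -> np.ndarray:
    """Per-vertex local tension map (nN/um), virial-style estimator.

    Vertex tension = sum over incident edges of (edge tension * edge length)
    divided by twice the vertex area (one third of incident deformed
    triangle areas).
    """
    X = system.positions
    e0, e1 = system.edges[:, 0], system.edges[:, 1]
    vec = X[e0] - X[e1]
    l = np.linalg.norm(vec, axis=1)
    f = system.config.spring_k * (l - system.rest_lengths)
    contrib = f * l
    num = np.zeros(system.n_vertices)
    np.add.at(num, e0, contrib)
    np.add.at(num, e1, contrib)
    # deformed areas
    area = np.zeros(system.n_vertices)
    t = system.triangles
    a = X[t[:, 1]] - X[t[:, 0]]
    b = X[t[:, 2]] - X[t[:, 0]]
    tri_area = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
    for i in range(3):
        np.add.at(area, t[:, i], tri_area / 3.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tension = num / (2.0 * 2.0 * area)
    tension[area <= 0] = 0.0
    return tension


def tension_profile(
    system: MembraneSystem,
    tension: np.ndarray,
    *,
    baseline: float | np.ndarray = 0.0,
    n_bins: int = 12,
    uniform_tol: float = 1e-9,
) -> TensionProfile:
    """Radial tension-change profile outside the pipette ring.

    ``baseline`` is the resting tension: either a scalar or the per-vertex
    map of the unloaded system (the latter cancels frozen mesh disorder and
    gives a much cleaner change profile).  The
    confinement length is the distance beyond the ring at which the change
    first falls below 10% of its peak; a flat map yields no confinement
    estimate (``confinement_um=None``).
    """
    cfg = system.config
    r = np.hypot(system.ref_positions[:, 0], system.ref_positions[:, 1])
    sel = (r > cfg.pipette_radius_um + cfg.ring_half_width_um) & ~system.fixed
    if not sel.any():
        raise ValueError("no vertices outside the ring")
    r_out = r[sel]
    base = np.asarray(baseline)
    dT = tension[sel] - (base[sel] if base.ndim else base)
    edges = np.linspace(r_out.min(), r_out.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prof = np.full(n_bins, np.nan)
    for i in range(n_bins):
        m = (r_out >= edges[i]) & (r_out < edges[i + 1] + (i == n_bins - 1))
        if m.any():
            prof[i] = dT[m].mean()
    valid = np.isfinite(prof)
    centers, prof = centers[valid], prof[valid]
    peak = float(np.nanmax(prof)) if len(prof) else np.nan
    if not np.isfinite(peak) or peak <= uniform_tol:
        return TensionProfile(centers, prof, peak, None, np.nan)
    peak_idx = int(np.nanargmax(prof))
    confinement = None
    for i in range(peak_idx + 1, len(prof)):
        if prof[i] < 0.1 * peak:
            confinement = float(centers[i] - cfg.pipette_radius_um)
            break
    far_frac = float(prof[-1] / peak)
    return TensionProfile(centers, prof, peak, confinement, far_frac)
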