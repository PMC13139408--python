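"""Construction of the starting state (43%-epiboly cap, ~660 cells).

The initializer over-fills the whole sphere with uniformly random cells of
the computed radius, equilibrates them under repulsion plus yolk
containment, bonds every cell to at least five nearby cells, then trims:
cells vegetal of the starting latitude are deleted, the animal-side cells
bonded to a deleted cell become the margin, and the margin bonds are cleaned
up into a single ring in azimuthal order.  The surviving cell count is
stochastic around the configured target.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .config import Config
from .forces import NeighborCache, global_pair_forces, integrate_step
from .geometry import polar_angles, stage_to_polar
from .state import SimulationState


class InitializationError(RuntimeError):
    pass


def compute_cell_radius(cfg: Config) -> float:
    """Radius r such that the target cell count tiles the starting cap:
    n * pi * r^2 = 4 * pi * R^2 * p, i.e. r = 2 R sqrt(p / n)."""
    return 2.0 * cfg.embryo_radius * math.sqrt(
        cfg.epiboly_initial_percentage / cfg.epiboly_initial_num_evl_cells
    )


def _uniform_sphere(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v


def _equilibrate(state: SimulationState, cfg: Config, max_steps: int) -> None:
    """Relax under the global potentials until the mean per-step displacement
    drops below tolerance."""
    cache = NeighborCache()
    for _ in range(max_steps):
        f = global_pair_forces(state, cfg, cache.pairs(state))
        before = state.pos.copy()
        integrate_step(state, f, cfg.dt)
        if float(np.mean(np.linalg.norm(state.pos - before, axis=1))) < cfg.equilibration_tol:
            break


def _bond_min_degree(state: SimulationState, cfg: Config, min_degree: int) -> None:
    """Bond each cell to its nearest cells until the global minimum degree
    reaches ``min_degree``, capped at 2.5x the spring rest length."""
    tree = cKDTree(state.pos)
    cap = 2.5 * 2.0 * float(state.cell_radius.max())
    k = min_degree + 4
    for _ in range(4):
        short = [i for i in range(state.n_cells) if state.degree(i) < min_degree]
        if not short:
            return
        kk = min(k, state.n_cells)
        dists, idx = tree.query(state.pos[short], k=kk)
        for row, i in enumerate(short):
            for dist, j in zip(dists[row], idx[row]):
                j = int(j)
                if j == i or j in state.adjacency[i]:
                    continue
                if dist > cap and state.degree(i) >= min_degree:
                    break
                state.add_bond(i, j)
                if state.degree(i) >= min_degree:
                    break
        k *= 2
    short = [i for i in range(state.n_cells) if state.degree(i) < min_degree]
    if short:
        raise InitializationError(f"could not reach min degree for cells {short[:5]}")


def _trim_and_ring(state: SimulationState, cfg: Config) -> SimulationState:
    """Delete vegetal-side cells, designate the graph boundary as the margin,
    and rebuild the margin bonds as a single azimuthally ordered ring."""
    phi_cut = stage_to_polar(cfg.epiboly_initial_percentage)
    phi = polar_angles(state.pos)
    above = phi <= phi_cut
    if above.sum() < 10:
        raise InitializationError("starting cap holds too few cells")

    # margin = graph-theory boundary of the kept subset
    boundary = np.zeros(state.n_cells, dtype=bool)
    for i in np.flatnonzero(above):
        if any(not above[j] for j in state.adjacency[i]):
            boundary[i] = True

    keep = np.flatnonzero(above)
    remap = -np.ones(state.n_cells, dtype=int)
    remap[keep] = np.arange(len(keep))

    new = SimulationState(
        positions=state.pos[keep],
        cell_radii=state.cell_radius[keep],
        drags=state.drag[keep],
        is_margin=boundary[keep],
        particle_radius=state.particle_radius,
        yolk_radius=state.yolk_radius,
    )
    for a, b in state.iter_bonds():
        if above[a] and above[b]:
            new.add_bond(int(remap[a]), int(remap[b]))

    # ring cleanup: drop all margin-margin bonds, re-link in theta order
    margin = new.margin_ids()
    if len(margin) < 3:
        raise InitializationError("margin ring has fewer than 3 cells")
    for a in margin:
        for b in list(new.adjacency[a]):
            if new.is_margin[b]:
                new.remove_bond(int(a), int(b))
    theta = np.arctan2(new.pos[margin, 1], new.pos[margin, 0])
    ring = margin[np.argsort(theta)]
    for i in range(len(ring)):
        new.add_bond(int(ring[i]), int(ring[(i + 1) % len(ring)]))
    return new


def _repair_degrees(state: SimulationState, cfg: Config) -> None:
    """Post-trim cleanup: restore the minimum bond count and the ceiling of
    margin bonds per internal cell."""
    tree = cKDTree(state.pos)
    for i in range(state.n_cells):
        while state.degree(i) < cfg.min_bonds:
            k = state.degree(i) + 6
            _, idx = tree.query(state.pos[i], k=min(k, state.n_cells))
            added = False
            for j in np.atleast_1d(idx):
                j = int(j)
                if j == i or j in state.adjacency[i]:
                    continue
                if state.is_margin[i] and state.is_margin[j]:
                    continue  # never create extra ring bonds
                state.add_bond(i, j)
                added = True
                break
            if not added:
                raise InitializationError(f"cannot repair degree of cell {i}")
    # margin-bond ceiling: shed the farthest excess margin bonds, topping up
    # either endpoint with a nearest internal partner if shedding would drop
    # it below the bond floor
    def _top_up(i: int) -> None:
        while state.degree(i) <= cfg.min_bonds:
            k = state.degree(i) + 8
            _, idx = tree.query(state.pos[i], k=min(k, state.n_cells))
            added = False
            for j in np.atleast_1d(idx):
                j = int(j)
                if j == i or j in state.adjacency[i] or state.is_margin[j]:
                    continue
                if state.margin_bond_count(j) >= cfg.max_margin_bonds_per_internal \
                        and state.is_margin[i]:
                    continue
                state.add_bond(i, j)
                added = True
                break
            if not added:
                raise InitializationError(f"cannot top up bonds of cell {i}")

    for i in range(state.n_cells):
        if state.is_margin[i]:
            continue
        mb = [j for j in state.adjacency[i] if state.is_margin[j]]
        if len(mb) <= cfg.max_margin_bonds_per_internal:
            continue
        mb.sort(key=lambda j: float(np.linalg.norm(state.pos[j] - state.pos[i])))
        for j in mb[cfg.max_margin_bonds_per_internal:]:
            _top_up(int(j))
            _top_up(i)
            state.remove_bond(i, int(j))


def initialize(cfg: Config, rng: np.random.Generator) -> SimulationState:
    """Build the equilibrated, bonded, trimmed starting state."""
    r_cell = compute_cell_radius(cfg)
    n_overfill = int(round(cfg.epiboly_initial_num_evl_cells / cfg.epiboly_initial_percentage))
    radius = cfg.embryo_radius

    positions = _uniform_sphere(n_overfill, radius, rng)
    state = SimulationState(
        positions=positions,
        cell_radii=np.full(n_overfill, r_cell),
        drags=np.ones(n_overfill),
        is_margin=np.zeros(n_overfill, dtype=bool),
        particle_radius=cfg.evl_particle_radius,
        yolk_radius=cfg.yolk_radius,
    )
    _equilibrate(state, cfg, cfg.equilibration_max_steps)
    _bond_min_degree(state, cfg, cfg.min_init_bonds)
    # settle the bonded network briefly before trimming
    _equilibrate(state, cfg, cfg.equilibration_max_steps // 4)

    state = _trim_and_ring(state, cfg)
    _repair_degrees(state, cfg)

    problems = state.validate_topology(cfg.min_bonds, cfg.max_margin_bonds_per_internal)
    if problems:
        raise InitializationError("; ".join(problems[:5]))
    return state
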