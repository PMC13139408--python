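"""Calibrated, area-coupled stochastic cell division.

The division rate is fixed at initialization so that the configured total
number of divisions (412 by default) accumulates, in expectation, by the
time the leading edge reaches the cessation stage (55% epiboly): the rate is
divisions per unit of EVL area increase, with EVL area taken as the
spherical-cap area implied by the current mean margin polar angle.  Each
step the expected count is rate * area increase and the realized count is a
Poisson draw.  Cells divide at most once; daughters take cell radius and
drag scaled by sqrt(2)/2, halving the apical area while keeping epithelial
thickness fixed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .config import Config
from .geometry import polar_to_stage, spherical_cap_area, stage_to_polar
from .state import SimulationState

DAUGHTER_SCALE = math.sqrt(2.0) / 2.0


def division_rate(cfg: Config, initial_stage: float | None = None) -> float:
    """Divisions per unit of EVL cap-area increase between the initial and
    cessation stages."""
    p0 = cfg.epiboly_initial_percentage if initial_stage is None else initial_stage
    p1 = cfg.cell_division_cessation_percentage
    if p1 <= p0:
        raise ValueError("cessation stage must exceed the initial stage")
    r = cfg.embryo_radius
    d_area = spherical_cap_area(r, p1) - spherical_cap_area(r, p0)
    return cfg.total_epiboly_divisions / d_area


def divisions_this_step(
    area_increase: float,
    rate: float,
    rng: np.random.Generator,
    stage: float,
    cessation_stage: float,
) -> int:
    """Poisson draw with mean rate * max(area_increase, 0); zero after the
    cessation stage."""
    if stage >= cessation_stage:
        return 0
    lam = rate * max(area_increase, 0.0)
    if lam == 0.0:
        return 0
    return int(rng.poisson(lam))


def evl_cap_area(state: SimulationState, embryo_radius: float) -> float:
    """Spherical-cap area implied by the current mean margin polar angle."""
    return spherical_cap_area(embryo_radius, polar_to_stage(state.mean_margin_phi()))


def _bond_new_daughter(
    state: SimulationState,
    d: int,
    cfg: Config,
    margin_only_internal: bool,
    min_bonds: int = 3,
) -> None:
    """Bond a fresh daughter to its nearest neighbors (the initializer's
    rule, with a minimum of three partners)."""
    tree = cKDTree(state.pos)
    cap = 2.5 * 2.0 * float(state.cell_radius[d])
    # generous candidate pool; grow if the neighborhood is sparse
    for k in (10, 25, 60):
        dists, idx = tree.query(state.pos[d], k=min(k, state.n_cells))
        added = 0
        for dist, j in zip(np.atleast_1d(dists), np.atleast_1d(idx)):
            j = int(j)
            if j == d or j in state.adjacency[d]:
                continue
            if margin_only_internal and state.is_margin[j]:
                continue  # a margin daughter's extra bonds go to internal cells
            if not state.is_margin[d] and state.is_margin[j] and \
                    state.margin_bond_count(d) >= cfg.max_margin_bonds_per_internal:
                continue
            if dist > cap and len(state.adjacency[d]) >= min_bonds:
                break
            state.add_bond(d, j)
            added += 1
            if len(state.adjacency[d]) >= min_bonds:
                break
        if len(state.adjacency[d]) >= min_bonds:
            return


def split_cell(
    state: SimulationState,
    cell: int,
    cfg: Config,
    rng: np.random.Generator,
) -> int:
    """Split ``cell`` into two side-by-side daughters; returns the new id.

    The division axis is a uniformly random in-sheet direction for internal
    cells and horizontal (equal polar angle) for margin cells, whose two
    daughters are inserted adjacently in the margin ring.  The parent keeps
    its bonds (rest lengths follow the updated radii implicitly); the new
    daughter is bonded to at least three nearest neighbors.
    """
    if state.has_divided[cell]:
        raise ValueError(f"cell {cell} has already divided")
    p = state.pos[cell]
    r = np.linalg.norm(p)
    rhat = p / r
    if state.is_margin[cell]:
        # horizontal: along the local azimuthal direction (constant phi)
        axis = np.cross([0.0, 0.0, 1.0], rhat)
        axis /= np.linalg.norm(axis)
    else:
        # uniform random direction in the local tangent plane
        e1 = np.cross([0.0, 0.0, 1.0], rhat)
        n1 = np.linalg.norm(e1)
        if n1 < 1e-9:
            e1 = np.cross([1.0, 0.0, 0.0], rhat)
            n1 = np.linalg.norm(e1)
        e1 /= n1
        e2 = np.cross(rhat, e1)
        alpha = rng.uniform(0.0, 2.0 * math.pi)
        axis = math.cos(alpha) * e1 + math.sin(alpha) * e2

    new_radius = float(state.cell_radius[cell]) * DAUGHTER_SCALE
    new_drag = float(state.drag[cell]) * DAUGHTER_SCALE
    offset = 0.5 * new_radius * axis

    was_margin = bool(state.is_margin[cell])
    daughter = state.add_cell(
        position=p + offset,
        cell_radius=new_radius,
        drag=new_drag,
        margin=was_margin,
        label=int(state.label[cell]),
        has_divided=True,
    )
    state.pos[cell] = p - offset
    state.cell_radius[cell] = new_radius
    state.drag[cell] = new_drag
    state.has_divided[cell] = True

    if was_margin:
        ring_nbrs = [j for j in state.adjacency[cell] if state.is_margin[j]]
        # insertion side is arbitrary; randomize it
        side = ring_nbrs[int(rng.integers(len(ring_nbrs)))]
        state.remove_bond(cell, side)
        state.add_bond(daughter, cell)
        state.add_bond(daughter, side)
        _bond_new_daughter(state, daughter, cfg, margin_only_internal=True)
    else:
        _bond_new_daughter(state, daughter, cfg, margin_only_internal=False)

    state.cum_div += 1
    return daughter


def division_step(
    state: SimulationState,
    cfg: Config,
    rate: float,
    prev_area: float,
    rng: np.random.Generator,
) -> tuple[int, float, list[tuple[int, int]]]:
    """One per-timestep division pass.

    ``prev_area`` is the running maximum EVL area: measuring each step's
    increase against it (rather than the last step's value) keeps step-to-
    step fluctuations of the mean margin angle from rectifying into spurious
    expected divisions.  Returns (number of divisions, updated running
    maximum, list of (parent, daughter) pairs)."""
    area = evl_cap_area(state, cfg.yolk_radius + state.particle_radius)
    stage = polar_to_stage(state.mean_margin_phi())
    n_div = divisions_this_step(
        area - prev_area, rate, rng, stage, cfg.cell_division_cessation_percentage
    )
    area = max(area, prev_area)
    pairs: list[tuple[int, int]] = []
    if n_div > 0:
        undivided = np.flatnonzero(~state.has_divided)
        n_div = min(n_div, len(undivided))
        chosen = rng.choice(undivided, size=n_div, replace=False)
        for c in chosen:
            d = split_cell(state, int(c), cfg, rng)
            pairs.append((int(c), d))
    return n_div, area, pairs
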