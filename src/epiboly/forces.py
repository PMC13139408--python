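"""Pairwise potentials, exogenous edge forces, and overdamped integration.

Three force classes act on EVL cells:

* bonded adhesion — attract-only harmonic springs on every bonded pair, so
  that together with the global repulsion a bonded pair feels exactly one
  full spring (no double-counted repulsion);
* global volume exclusion — repel-only harmonic springs between every EVL
  pair closer than the sum of their cell radii, bonded or not;
* yolk containment — a full harmonic spring between each EVL cell and the
  pinned yolk center, with rest length set by the particle (not cell) radii.

The exogenous pulling force acts on margin cells only, tangent to the embryo
surface toward the vegetal pole.  Model 1 applies a constant force per radian
of leading-edge azimuthal arc; Model 2 reweights it by each cell's distance
from the vegetal pole (negative feedback: lagging cells are pulled harder).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import Config
from .geometry import azimuth_angles, polar_angles, vegetal_tangents, wrapped_dtheta
from .state import SimulationState


class NumericalBlowupError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# single-pair spring (reference implementation; the step function below is
# the vectorized equivalent)
# ---------------------------------------------------------------------------

def pair_spring_force(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    k: float,
    rest_length: float,
    mode: str = "full",
) -> np.ndarray:
    """Harmonic force on particle *a* from its pair with *b*.

    ``mode`` selects the active side of the rest length: ``full`` acts on
    both sides, ``repel_only`` only under compression (d < rest), and
    ``attract_only`` only under extension (d > rest).
    """
    if mode not in ("full", "repel_only", "attract_only"):
        raise ValueError(f"unknown mode {mode!r}")
    d = np.asarray(pos_b, float) - np.asarray(pos_a, float)
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        raise ValueError("coincident positions")
    stretch = dist - rest_length
    if mode == "repel_only" and stretch >= 0.0:
        return np.zeros(3)
    if mode == "attract_only" and stretch <= 0.0:
        return np.zeros(3)
    # positive stretch pulls a toward b; negative pushes away
    return k * stretch * (d / dist)


# ---------------------------------------------------------------------------
# neighbor search for the global repulsion
# ---------------------------------------------------------------------------

class NeighborCache:
    """Cell-pair list within a padded cutoff, rebuilt only after sufficient
    particle motion.  Repel-only forces vanish beyond the rest length, so a
    cutoff of the maximum rest length plus padding is exact."""

    def __init__(self, pad_fraction: float = 0.15):
        self.pad_fraction = pad_fraction
        self._pairs: np.ndarray | None = None
        self._built_pos: np.ndarray | None = None
        self._cutoff = 0.0
        self._pad = 0.0
        self._n = -1

    def pairs(self, state: SimulationState) -> np.ndarray:
        cutoff = 2.0 * float(state.cell_radius.max())
        pad = self.pad_fraction * cutoff
        rebuild = (
            self._pairs is None
            or self._n != state.n_cells
            or cutoff > self._cutoff
            or np.max(np.abs(state.pos - self._built_pos)) > pad / 2.0
        )
        if rebuild:
            tree = cKDTree(state.pos)
            self._pairs = tree.query_pairs(cutoff + pad, output_type="ndarray")
            self._built_pos = state.pos.copy()
            self._cutoff = cutoff
            self._pad = pad
            self._n = state.n_cells
        return self._pairs


# ---------------------------------------------------------------------------
# global (non-exogenous) forces
# ---------------------------------------------------------------------------

def global_pair_forces(
    state: SimulationState,
    cfg: Config,
    neighbor_pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Accumulated per-cell force from repulsion, adhesion, and containment."""
    n = state.n_cells
    f = np.zeros((n, 3))

    # repel-only springs between every close EVL pair
    if neighbor_pairs is None:
        tree = cKDTree(state.pos)
        neighbor_pairs = tree.query_pairs(
            2.0 * float(state.cell_radius.max()), output_type="ndarray"
        )
    if len(neighbor_pairs):
        a, b = neighbor_pairs[:, 0], neighbor_pairs[:, 1]
        d = state.pos[b] - state.pos[a]
        dist = np.linalg.norm(d, axis=1)
        rest = state.cell_radius[a] + state.cell_radius[b]
        overlap = rest - dist
        active = (overlap > 0.0) & (dist > 0.0)
        if np.any(active):
            mag = cfg.harmonic_repulsion_spring_constant * overlap[active]
            fv = (mag / dist[active])[:, None] * d[active]
            np.subtract.at(f, a[active], fv)
            np.add.at(f, b[active], fv)

    # attract-only springs on bonded pairs
    pairs, edge = state.bond_arrays()
    if len(pairs):
        a, b = pairs[:, 0], pairs[:, 1]
        d = state.pos[b] - state.pos[a]
        dist = np.linalg.norm(d, axis=1)
        rest = state.cell_radius[a] + state.cell_radius[b]
        stretch = dist - rest
        k = np.where(edge, cfg.harmonic_edge_spring_constant, cfg.harmonic_spring_constant)
        active = stretch > 0.0
        if np.any(active):
            mag = k[active] * stretch[active]
            fv = (mag / dist[active])[:, None] * d[active]
            np.add.at(f, a[active], fv)
            np.subtract.at(f, b[active], fv)

    # full spring between each EVL cell and the yolk center (pinned)
    if cfg.harmonic_yolk_evl_spring_constant > 0.0:
        r = np.linalg.norm(state.pos, axis=1)
        rest_yolk = state.yolk_radius + state.particle_radius
        mag = cfg.harmonic_yolk_evl_spring_constant * (r - rest_yolk)
        f -= (mag / r)[:, None] * state.pos
    return f


# ---------------------------------------------------------------------------
# exogenous edge forces
# ---------------------------------------------------------------------------

@dataclass
class EdgeForceAssignment:
    """Per-margin-cell exogenous force, in margin-ring order."""

    ring: list[int]          # margin cell ids, cyclic order
    weights: np.ndarray      # L_i (Model 1) or normalized W'_i (Model 2), radians
    forces: np.ndarray       # (m, 3) force vectors, parallel to vegetal tangents


def _edge_lengths(state: SimulationState, ring: list[int]) -> np.ndarray:
    """L_i: half the azimuthal angular distance to each bonded margin
    neighbor, summed — i.e. the azimuthal span between the two midlines.
    Signed wrapped steps telescope, so sum(L) = 2*pi exactly."""
    theta = azimuth_angles(state.pos[ring])
    steps = np.asarray(wrapped_dtheta(np.roll(theta, -1), theta))  # i -> i+1
    return 0.5 * (steps + np.roll(steps, 1))


def edge_forces_model1(state: SimulationState, cfg: Config) -> EdgeForceAssignment:
    """Uniform force per unit (angular) length of leading edge: F_i = F * L_i."""
    ring = state.margin_ring()
    lengths = _edge_lengths(state, ring)
    tangents = vegetal_tangents(state.pos[ring])
    forces = (cfg.force_per_unit_length * lengths)[:, None] * tangents
    return EdgeForceAssignment(ring=ring, weights=lengths, forces=forces)


def edge_forces_model2(state: SimulationState, cfg: Config) -> EdgeForceAssignment:
    """Force-regulated variant: raw weight W_i = L_i * (pi - phi_i) favors
    lagging cells; weights are rescaled to sum to the leading-edge
    circumference at the mean margin polar angle, 2*pi*R*sin(mean phi) on
    the EVL mid-surface (R = yolk radius + particle radius)."""
    ring = state.margin_ring()
    lengths = _edge_lengths(state, ring)
    phi = polar_angles(state.pos[ring])
    raw = lengths * (math.pi - phi)
    total = float(raw.sum())
    if total <= 0.0:
        raise ValueError("degenerate edge-force weights: margin at the vegetal pole")
    radius = state.yolk_radius + state.particle_radius
    circumference = 2.0 * math.pi * radius * math.sin(float(np.mean(phi)))
    weights = raw * (circumference / total)
    tangents = vegetal_tangents(state.pos[ring])
    forces = (cfg.force_per_unit_length * weights)[:, None] * tangents
    return EdgeForceAssignment(ring=ring, weights=weights, forces=forces)


def edge_forces(state: SimulationState, cfg: Config) -> EdgeForceAssignment:
    if cfg.force_regulation_enabled:
        return edge_forces_model2(state, cfg)
    return edge_forces_model1(state, cfg)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_step(state: SimulationState, forces: np.ndarray, dt: float) -> None:
    """Explicit overdamped update: displacement = (force / drag) * dt.

    The yolk is pinned and not represented in the arrays; every EVL cell is
    mobile.  Raises on non-finite forces (numerical blowup).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(forces)):
        raise NumericalBlowupError("non-finite force encountered")
    state.pos += (forces / state.drag[:, None]) * dt
    state.time += dt
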