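"""Particle/cell data model and the dynamic bond graph.

Cells are stored column-wise in numpy arrays indexed by integer cell id;
bonds live in an adjacency list of sets.  The yolk is not a row in these
arrays: it is pinned at the origin and interacts with the EVL only through
the analytic containment spring, so the state tracks its radii as scalars.

A bond's rest length is always the sum of the two cell radii, and its spring
constant is determined by its kind (edge if both endpoints are margin cells,
interior otherwise), so bonds need no per-bond storage beyond adjacency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import azimuth_angles, polar_angles, wrapped_dtheta

INTERNAL = 0
MARGIN = 1

_KIND_NAMES = {INTERNAL: "internal", MARGIN: "margin"}
_KIND_CODES = {v: k for k, v in _KIND_NAMES.items()}


class TopologyError(RuntimeError):
    """Raised when the bond graph violates a structural invariant."""


@dataclass(frozen=True)
class Cell:
    """Read-only view of one cell's fields."""

    id: int
    kind: str
    position: np.ndarray
    cell_radius: float
    particle_radius: float
    drag: float
    has_divided: bool
    label: int


@dataclass(frozen=True)
class Bond:
    """Read-only view of one adhesion spring."""

    cell_a: int
    cell_b: int
    spring_constant: float
    rest_length: float
    kind: str  # "interior" | "edge"


class SimulationState:
    """EVL cells + bond graph + clock + cumulative event counters."""

    def __init__(
        self,
        positions: np.ndarray,
        cell_radii: np.ndarray,
        drags: np.ndarray,
        is_margin: np.ndarray,
        particle_radius: float,
        yolk_radius: float,
    ) -> None:
        n = len(positions)
        self.pos = np.asarray(positions, dtype=float).reshape(n, 3).copy()
        self.cell_radius = np.asarray(cell_radii, dtype=float).copy()
        self.drag = np.asarray(drags, dtype=float).copy()
        self.is_margin = np.asarray(is_margin, dtype=bool).copy()
        self.has_divided = np.zeros(n, dtype=bool)
        self.label = np.zeros(n, dtype=np.int32)
        self.adjacency: list[set[int]] = [set() for _ in range(n)]
        self.particle_radius = float(particle_radius)
        self.yolk_radius = float(yolk_radius)
        self._bond_cache: tuple[np.ndarray, np.ndarray] | None = None
        self.timestep = 0
        self.time = 0.0
        self.cum_in = 0   # cells migrated into the margin
        self.cum_out = 0  # cells migrated out of the margin
        self.cum_div = 0  # divisions

    # -- basic queries ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.adjacency)

    def degree(self, i: int) -> int:
        return len(self.adjacency[i])

    def margin_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_margin)

    def margin_bond_count(self, i: int) -> int:
        return sum(1 for j in self.adjacency[i] if self.is_margin[j])

    def bonded(self, a: int, b: int) -> bool:
        return b in self.adjacency[a]

    def is_edge_bond(self, a: int, b: int) -> bool:
        return bool(self.is_margin[a] and self.is_margin[b])

    def rest_length(self, a: int, b: int) -> float:
        return float(self.cell_radius[a] + self.cell_radius[b])

    def cell(self, i: int) -> Cell:
        return Cell(
            id=i,
            kind=_KIND_NAMES[MARGIN if self.is_margin[i] else INTERNAL],
            position=self.pos[i].copy(),
            cell_radius=float(self.cell_radius[i]),
            particle_radius=self.particle_radius,
            drag=float(self.drag[i]),
            has_divided=bool(self.has_divided[i]),
            label=int(self.label[i]),
        )

    def iter_bonds(self):
        for a, nbrs in enumerate(self.adjacency):
            for b in nbrs:
                if a < b:
                    yield a, b

    def bond_view(self, a: int, b: int, k_interior: float, k_edge: float) -> Bond:
        edge = self.is_edge_bond(a, b)
        return Bond(
            cell_a=a,
            cell_b=b,
            spring_constant=k_edge if edge else k_interior,
            rest_length=self.rest_length(a, b),
            kind="edge" if edge else "interior",
        )

    # -- mutation -----------------------------------------------------------
    def add_bond(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("cannot bond a cell to itself")
        self.adjacency[a].add(b)
        self.adjacency[b].add(a)
        self._bond_cache = None

    def remove_bond(self, a: int, b: int) -> None:
        self.adjacency[a].discard(b)
        self.adjacency[b].discard(a)
        self._bond_cache = None

    def add_cell(
        self,
        position: np.ndarray,
        cell_radius: float,
        drag: float,
        margin: bool,
        label: int = 0,
        has_divided: bool = False,
    ) -> int:
        i = self.n_cells
        self.pos = np.vstack([self.pos, np.asarray(position, float).reshape(1, 3)])
        self.cell_radius = np.append(self.cell_radius, cell_radius)
        self.drag = np.append(self.drag, drag)
        self.is_margin = np.append(self.is_margin, margin)
        self.has_divided = np.append(self.has_divided, has_divided)
        self.label = np.append(self.label, np.int32(label))
        self.adjacency.append(set())
        self._bond_cache = None
        return i

    # -- bond arrays for vectorized force evaluation -------------------------
    def bond_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(m, 2) array of bonded pairs (a < b) and an (m,) edge-kind mask.

        Cached until the topology changes (positions may move freely)."""
        if self._bond_cache is not None:
            return self._bond_cache
        pairs = [(a, b) for a, nbrs in enumerate(self.adjacency) for b in nbrs if a < b]
        if not pairs:
            out = (np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=bool))
        else:
            arr = np.asarray(pairs, dtype=np.int64)
            edge = self.is_margin[arr[:, 0]] & self.is_margin[arr[:, 1]]
            out = (arr, edge)
        self._bond_cache = out
        return out

    # -- margin ring ----------------------------------------------------------
    def margin_ring(self) -> list[int]:
        """The margin cycle as an ordered list, oriented toward increasing theta.

        Starts at the margin cell with the smallest id.  Raises
        :class:`TopologyError` if the margin subgraph is not a single simple
        cycle with every margin cell holding exactly two margin neighbors.
        """
        margin = self.margin_ids()
        m = len(margin)
        if m < 3:
            raise TopologyError(f"margin has only {m} cells")
        ring_nbrs: dict[int, list[int]] = {}
        for i in margin:
            nbrs = [j for j in self.adjacency[i] if self.is_margin[j]]
            if len(nbrs) != 2:
                raise TopologyError(
                    f"margin cell {i} has {len(nbrs)} margin neighbors (expected 2)"
                )
            ring_nbrs[int(i)] = nbrs
        start = int(margin[0])
        ring = [start]
        prev = start
        cur = int(ring_nbrs[start][0])
        while cur != start:
            ring.append(cur)
            if len(ring) > m:
                raise TopologyError("margin subgraph is not a single cycle")
            a, b = ring_nbrs[cur]
            nxt = b if a == prev else a
            prev, cur = cur, int(nxt)
        if len(ring) != m:
            raise TopologyError("margin subgraph has more than one cycle")
        # orient toward increasing theta: total wrapped winding must be +2*pi
        theta = azimuth_angles(self.pos[ring])
        winding = float(np.sum(wrapped_dtheta(np.roll(theta, -1), theta)))
        if winding < 0:
            ring = [start] + ring[:0:-1]
        return ring

    # -- validation -----------------------------------------------------------
    def validate_topology(self, min_bonds: int = 3, max_margin_bonds: int = 3) -> list[str]:
        """Report all bond-graph invariant violations (empty list = valid)."""
        problems: list[str] = []
        # bond symmetry
        for a, nbrs in enumerate(self.adjacency):
            for b in nbrs:
                if a not in self.adjacency[b]:
                    problems.append(f"asymmetric bond {a}->{b}")
        # margin ring is a single simple cycle
        try:
            self.margin_ring()
        except TopologyError as exc:
            problems.append(str(exc))
        # degree floor and margin-bond ceiling
        for i in range(self.n_cells):
            if self.degree(i) < min_bonds:
                problems.append(f"cell {i} has {self.degree(i)} bonds (< {min_bonds})")
            if not self.is_margin[i] and self.margin_bond_count(i) > max_margin_bonds:
                problems.append(
                    f"internal cell {i} bonded to {self.margin_bond_count(i)} margin cells"
                )
        return problems

    # -- measurements used across modules --------------------------------------
    def mean_margin_phi(self) -> float:
        return float(np.mean(polar_angles(self.pos[self.is_margin])))

    def adjacent_bond_angles(self, cell: int, neighbor_a: int, neighbor_b: int) -> float:
        """Angle at ``cell`` between its 3D bond vectors to the two neighbors."""
        if neighbor_a not in self.adjacency[cell] or neighbor_b not in self.adjacency[cell]:
            raise ValueError("both neighbors must be bonded to the cell")
        va = self.pos[neighbor_a] - self.pos[cell]
        vb = self.pos[neighbor_b] - self.pos[cell]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0.0 or nb == 0.0:
            raise ValueError("zero-length bond vector")
        return float(math.acos(float(np.clip(va @ vb / (na * nb), -1.0, 1.0))))

    # -- serialization ----------------------------------------------------------
    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_cells),
                "kind": ["margin" if m else "internal" for m in self.is_margin],
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "z": self.pos[:, 2],
                "cell_radius": self.cell_radius,
                "drag": self.drag,
                "has_divided": self.has_divided,
                "label": self.label,
            }
        )

    def bonds_frame(self, k_interior: float = 0.5, k_edge: float = 0.5) -> pd.DataFrame:
        pairs, edge = self.bond_arrays()
        k = np.where(edge, k_edge, k_interior)
        rest = self.cell_radius[pairs[:, 0]] + self.cell_radius[pairs[:, 1]] \
            if len(pairs) else np.empty(0)
        return pd.DataFrame(
            {
                "a": pairs[:, 0] if len(pairs) else [],
                "b": pairs[:, 1] if len(pairs) else [],
                "k": k,
                "rest_length": rest,
                "kind": np.where(edge, "edge", "interior"),
            }
        )

    def save(self, directory: str | Path, config_dict: dict | None = None) -> None:
        """Write the standard snapshot: cells CSV + bonds CSV + JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells_frame().to_csv(directory / "cells.csv", index=False)
        self.bonds_frame().to_csv(directory / "bonds.csv", index=False)
        manifest = {
            "timestep": self.timestep,
            "time": self.time,
            "n_cells": self.n_cells,
            "counters": {
                "in_migrations": self.cum_in,
                "out_migrations": self.cum_out,
                "divisions": self.cum_div,
            },
            "particle_radius": self.particle_radius,
            "yolk_radius": self.yolk_radius,
        }
        if config_dict is not None:
            manifest["config"] = config_dict
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory: str | Path) -> "SimulationState":
        directory = Path(directory)
        cells = pd.read_csv(directory / "cells.csv")
        bonds = pd.read_csv(directory / "bonds.csv")
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        state = cls(
            positions=cells[["x", "y", "z"]].to_numpy(),
            cell_radii=cells["cell_radius"].to_numpy(),
            drags=cells["drag"].to_numpy(),
            is_margin=(cells["kind"] == "margin").to_numpy(),
            particle_radius=manifest["particle_radius"],
            yolk_radius=manifest["yolk_radius"],
        )
        state.has_divided = cells["has_divided"].to_numpy(dtype=bool)
        state.label = cells["label"].to_numpy(dtype=np.int32)
        for a, b in bonds[["a", "b"]].to_numpy(dtype=int):
            state.add_bond(int(a), int(b))
        state.timestep = int(manifest["timestep"])
        state.time = float(manifest["time"])
        counters = manifest["counters"]
        state.cum_in = int(counters["in_migrations"])
        state.cum_out = int(counters["out_migrations"])
        state.cum_div = int(counters["divisions"])
        return state
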