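"""Run configuration.

All physical parameters carry the names used in the simulation's
configuration files.  Distances are in model distance units (the yolk
particle has diameter 6.0), forces in model force units, angles in radians
unless a field name says otherwise.  Percent-epiboly stages are stored as
fractions in [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


@dataclass
class Config:
    # --- initialization -------------------------------------------------
    #: target number of EVL cells at the starting stage; the realized count
    #: is stochastic around this value
    epiboly_initial_num_evl_cells: int = 660
    #: true leading-edge position of the stage conventionally called
    #: "30% epiboly", as a fraction of embryo surface covered
    epiboly_initial_percentage: float = 0.43
    #: yolk particle diameter, distance units
    yolk_diameter: float = 6.0
    #: EVL particle (render/containment) radius, distance units
    evl_particle_radius: float = 0.09
    #: minimum bonded neighbors guaranteed per cell at initialization
    min_init_bonds: int = 5
    #: convergence tolerance for equilibration: mean per-step displacement
    equilibration_tol: float = 1e-4
    #: hard cap on equilibration steps
    equilibration_max_steps: int = 4000

    # --- potentials and bonds -------------------------------------------
    harmonic_repulsion_spring_constant: float = 0.5
    harmonic_spring_constant: float = 0.5
    harmonic_edge_spring_constant: float = 0.5
    harmonic_yolk_evl_spring_constant: float = 4.0

    # --- bond-angle constraint ------------------------------------------
    lambda_bond_angle: float = 3.75
    lambda_edge_bond_angle: float = 4.0
    #: candidate-search radius for new bonds, in focal-cell diameters
    bond_search_factor: float = 2.0
    #: maximum distance of a margin-joining cell from the margin, in
    #: (mean) cell diameters
    join_distance_factor: float = 0.75
    #: minimum bonds any EVL cell must retain
    min_bonds: int = 3
    #: maximum bonds from one internal cell to margin cells
    max_margin_bonds_per_internal: int = 3

    # --- cell division ---------------------------------------------------
    cell_division_cessation_percentage: float = 0.55
    total_epiboly_divisions: int = 412

    # --- epiboly driving force -------------------------------------------
    force_per_unit_length: float = 0.7

    # --- model-variant flags ---------------------------------------------
    cell_division_enabled: bool = True
    force_regulation_enabled: bool = True
    bond_remodeling_enabled: bool = True

    # --- integration and termination -------------------------------------
    #: integration step; chosen for stability of the explicit overdamped
    #: update (dt * k_max / drag_min well below 1)
    dt: float = 0.025
    #: physics integrations per event step (remodeling/division cadence);
    #: the default keeps full runs in the same few-thousand-step range as
    #: the remodeling cadence assumes (one sweep per cell per step)
    substeps: int = 1
    #: stop when the mean margin polar angle reaches this value (radians)
    termination_phi: float = 0.95 * math.pi
    #: without force regulation the margin can protrude; also stop when any
    #: single margin cell passes this polar angle
    protrusion_phi: float = 0.98 * math.pi
    #: hard cap on event steps
    max_steps: int = 50_000
    #: state-snapshot stride (event steps); metrics are recorded every step
    snapshot_stride: int = 25

    #: RNG seed; mandatory in run manifests
    seed: int = 0

    # ----------------------------------------------------------------------
    def __post_init__(self) -> None:
        if not 0.0 < self.epiboly_initial_percentage < 1.0:
            raise ValueError("epiboly_initial_percentage must be in (0, 1)")
        if self.epiboly_initial_num_evl_cells < 10:
            raise ValueError("need at least 10 EVL cells")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 < self.termination_phi < math.pi:
            raise ValueError("termination_phi must be in (0, pi)")

    @property
    def yolk_radius(self) -> float:
        return self.yolk_diameter / 2.0

    @property
    def embryo_radius(self) -> float:
        """Radius of the EVL mid-surface (yolk radius + particle radius)."""
        return self.yolk_radius + self.evl_particle_radius

    @property
    def embryo_diameter(self) -> float:
        return 2.0 * self.embryo_radius

    def mm_per_distance_unit(self, live_embryo_diameter_mm: float = 0.7) -> float:
        """Physical scale implied by a live embryo of the given diameter."""
        return live_embryo_diameter_mm / self.embryo_diameter

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def replace(self, **kwargs: Any) -> "Config":
        return dataclasses.replace(self, **kwargs)
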