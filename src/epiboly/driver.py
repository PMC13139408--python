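"""The per-timestep event loop, termination, and experiment protocols.

Each event step applies, in order: exogenous edge forces + overdamped
integration (possibly several physics substeps), the stochastic remodeling
sweep, calibrated cell division, and metrics recording.  A run terminates
when the mean margin polar angle reaches the configured termination value
(0.95*pi, ~99% epiboly), at the step cap, or — without force regulation,
where the margin typically develops a vegetal protrusion — when any single
margin cell passes the protrusion threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import division as div
from . import forces as frc
from . import metrics as met
from . import remodeling as rem
from .config import Config
from .geometry import polar_angles, polar_to_stage
from .initialization import initialize
from .state import SimulationState


@dataclass
class Trajectory:
    """A run's recorded output: per-step metrics, accepted events, snapshots
    (strided), and the final state."""

    config: Config
    metrics: pd.DataFrame
    events: pd.DataFrame
    snapshots: list[tuple[int, pd.DataFrame, pd.DataFrame]]
    final_state: SimulationState
    termination: str  # completed | protrusion | step_cap | phase_budget
    initial_margin_count: int = 0

    @property
    def records(self) -> pd.DataFrame:
        return self.metrics


def _apply_edge_forces(f: np.ndarray, assignment: frc.EdgeForceAssignment) -> None:
    f[assignment.ring] += assignment.forces


def _event_step(
    state: SimulationState,
    cfg: Config,
    rng: np.random.Generator,
    cache: frc.NeighborCache,
    exogenous: bool,
    remodeling: bool,
    division_on: bool,
    rate: float,
    prev_area: float,
    event_rows: list,
) -> float:
    """One event step; returns the updated EVL cap area."""
    for _ in range(cfg.substeps):
        f = frc.global_pair_forces(state, cfg, cache.pairs(state))
        if exogenous:
            _apply_edge_forces(f, frc.edge_forces(state, cfg))
        frc.integrate_step(state, f, cfg.dt)
    if remodeling:
        for ev in rem.remodel_sweep(state, cfg, rng):
            if ev.accepted:
                event_rows.append(
                    (state.timestep, ev.type, ev.focal, ev.partner, ev.delta_e)
                )
    area = prev_area
    if division_on:
        n_div, area, pairs = div.division_step(state, cfg, rate, prev_area, rng)
        for parent, daughter in pairs:
            event_rows.append((state.timestep, "division", parent, daughter, 0.0))
    state.timestep += 1
    return area


def _loop(
    state: SimulationState,
    cfg: Config,
    rng: np.random.Generator,
    *,
    exogenous: bool = True,
    remodeling: bool | None = None,
    division_on: bool | None = None,
    max_steps: int | None = None,
    termination_phi: float | None = None,
    check_protrusion: bool | None = None,
    records: list | None = None,
    event_rows: list | None = None,
    snapshots: list | None = None,
    phase: str = "epiboly",
) -> str:
    """Run event steps until a stopping condition; mutates ``state``."""
    remodeling = cfg.bond_remodeling_enabled if remodeling is None else remodeling
    division_on = cfg.cell_division_enabled if division_on is None else division_on
    max_steps = cfg.max_steps if max_steps is None else max_steps
    termination_phi = cfg.termination_phi if termination_phi is None else termination_phi
    if check_protrusion is None:
        check_protrusion = exogenous and not cfg.force_regulation_enabled
    records = [] if records is None else records
    event_rows = [] if event_rows is None else event_rows
    cache = frc.NeighborCache()
    # calibrate the division rate to the run's actual starting area, so the
    # configured total accumulates by the cessation stage in expectation
    rate = (
        div.division_rate(cfg, initial_stage=polar_to_stage(state.mean_margin_phi()))
        if division_on
        else 0.0
    )
    prev_area = div.evl_cap_area(state, cfg.embryo_radius)
    if not records:
        rec = met.measure(state, cfg)
        records.append((rec, phase))
    for _ in range(max_steps):
        prev_area = _event_step(
            state, cfg, rng, cache, exogenous, remodeling, division_on,
            rate, prev_area, event_rows,
        )
        rec = met.measure(state, cfg)
        records.append((rec, phase))
        if snapshots is not None and state.timestep % cfg.snapshot_stride == 0:
            snapshots.append((state.timestep, state.cells_frame(), state.bonds_frame()))
        if rec.mean_phi >= termination_phi:
            return "completed"
        if check_protrusion:
            if float(polar_angles(state.pos[state.is_margin]).max()) > cfg.protrusion_phi:
                return "protrusion"
    return "step_cap"


def _finalize(
    cfg: Config,
    state: SimulationState,
    records: list,
    event_rows: list,
    snapshots: list,
    termination: str,
    initial_margin: int,
) -> Trajectory:
    frame = met.records_frame([r for r, _ in records])
    frame["phase"] = [p for _, p in records]
    events = pd.DataFrame(
        event_rows, columns=["timestep", "type", "focal", "partner", "delta_e"]
    )
    return Trajectory(
        config=cfg,
        metrics=frame,
        events=events,
        snapshots=snapshots,
        final_state=state,
        termination=termination,
        initial_margin_count=initial_margin,
    )


def run(
    cfg: Config,
    rng: np.random.Generator | None = None,
    state: SimulationState | None = None,
    keep_snapshots: bool = False,
) -> Trajectory:
    """A full epiboly run from initialization to termination."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if state is None:
        state = initialize(cfg, rng)
    initial_margin = int(state.is_margin.sum())
    records: list = []
    event_rows: list = []
    snapshots: list = [] if keep_snapshots else None
    termination = _loop(
        state, cfg, rng,
        records=records, event_rows=event_rows, snapshots=snapshots,
    )
    return _finalize(
        cfg, state, records, event_rows, snapshots or [], termination, initial_margin
    )


def recoil_experiment(
    cfg: Config,
    rng: np.random.Generator | None = None,
    trigger_phi: float = 0.9 * math.pi,
    phase1_steps: int = 300,
    phase2_steps: int = 500,
    fixed_topology_control: bool = False,
) -> Trajectory:
    """Two-phase force-disruption protocol.

    A base run proceeds until the mean margin polar angle reaches
    ``trigger_phi``.  Phase 1 then disables both the exogenous forces and
    bond remodeling (instantaneous elastic response); phase 2 re-enables
    remodeling with forces still off (long-term response).  With
    ``fixed_topology_control`` remodeling is disabled from the start and the
    experiment has a single force-off phase — the purely elastic control,
    which recoils drastically.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if fixed_topology_control:
        cfg = cfg.replace(bond_remodeling_enabled=False)
    state = initialize(cfg, rng)
    initial_margin = int(state.is_margin.sum())
    records: list = []
    event_rows: list = []
    base = _loop(
        state, cfg, rng,
        termination_phi=trigger_phi,
        check_protrusion=False,
        records=records, event_rows=event_rows,
        phase="pull",
    )
    # release from wherever the pull phase ended (a capped elastic control
    # still recoils from its stretched state)
    _loop(
        state, cfg, rng,
        exogenous=False, remodeling=False, division_on=False,
        max_steps=phase1_steps, termination_phi=math.pi,
        check_protrusion=False,
        records=records, event_rows=event_rows, phase="release",
    )
    if not fixed_topology_control:
        _loop(
            state, cfg, rng,
            exogenous=False, remodeling=True, division_on=False,
            max_steps=phase2_steps, termination_phi=math.pi,
            check_protrusion=False,
            records=records, event_rows=event_rows, phase="remodel",
        )
    termination = "phase_budget" if base == "completed" else base
    return _finalize(cfg, state, records, event_rows, [], termination, initial_margin)


# ---------------------------------------------------------------------------
# lineage labeling
# ---------------------------------------------------------------------------

def label_lineage(state: SimulationState, spec: tuple, label: int = 1) -> SimulationState:
    """Permanently label a cell subset at initialization.

    ``spec`` is one of ``("margin",)``, ``("tier", k)`` (cells at graph
    distance k from the margin ring, excluding nearer tiers), or
    ``("patch", width_deg, height_deg)`` (an azimuthal window of the given
    angular size adjacent to the margin).
    """
    kind = spec[0]
    if kind == "margin":
        chosen = set(int(i) for i in state.margin_ids())
    elif kind == "tier":
        k = int(spec[1])
        dist = {int(i): 0 for i in state.margin_ids()}
        frontier = list(dist)
        d = 0
        while frontier and d < k:
            d += 1
            nxt = []
            for i in frontier:
                for j in state.adjacency[i]:
                    if j not in dist:
                        dist[int(j)] = d
                        nxt.append(int(j))
            frontier = nxt
        chosen = {i for i, dd in dist.items() if dd == k}
    elif kind == "patch":
        width = math.radians(float(spec[1]))
        height = math.radians(float(spec[2]))
        phi = polar_angles(state.pos)
        theta = np.arctan2(state.pos[:, 1], state.pos[:, 0])
        phi_edge = state.mean_margin_phi()
        sel = (
            (phi <= phi_edge)
            & (phi >= phi_edge - height)
            & (np.abs(theta) <= width / 2.0)
        )
        chosen = set(int(i) for i in np.flatnonzero(sel))
    else:
        raise ValueError(f"unknown lineage spec {spec!r}")
    if not chosen:
        raise ValueError("lineage selection is empty")
    for i in chosen:
        state.label[i] = label
    return state


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

def sweep(
    base: Config,
    param_values: dict[str, list],
    seeds: list[int],
    runner=run,
) -> dict[tuple, list[Trajectory]]:
    """Run replicates across the cartesian product of parameter settings.

    ``param_values`` maps config field names to value lists; a treatment is
    one combination.  Convenience patterns: a global bond-angle sweep sets
    both lambda fields equal; an edge-only sweep varies only
    ``lambda_edge_bond_angle``; the edge-spring sweep varies
    ``harmonic_edge_spring_constant``; the purse-string variant is Model 1
    with an increased edge spring constant.
    """
    import itertools

    names = list(param_values)
    results: dict[tuple, list[Trajectory]] = {}
    for combo in itertools.product(*(param_values[n] for n in names)):
        overrides = dict(zip(names, combo))
        trajs = []
        for seed in seeds:
            cfg = base.replace(seed=seed, **overrides)
            trajs.append(runner(cfg))
        results[tuple(combo)] = trajs
    return results


def lambda_global_sweep(base: Config, values: list[float], seeds: list[int]):
    """Vary the bond-angle constraint strength uniformly in edge and interior."""
    results = {}
    for lam in values:
        cfg = base.replace(lambda_bond_angle=lam, lambda_edge_bond_angle=lam)
        results[lam] = [run(cfg.replace(seed=s)) for s in seeds]
    return results
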