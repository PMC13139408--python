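"""Per-timestep measurements and replicate aggregation.

* stage — mean polar angle of the margin cells, and the percent-epiboly it
  implies;
* edge tension — median over edge bonds of the signed spring tension
  k (L - r0);
* lopsidedness — polar angle of the upward normal of the best-fit plane
  through the margin positions (0 for a synchronously advancing ring);
* Straightness Index (SI) — after rotating the frame so the margin best-fit
  plane is horizontal, the ring is mapped to (phi, theta) and SI is the
  beeline circumference 2*pi divided by the traversed path length, with the
  azimuthal seam handled by shortest wrapped differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config
from .geometry import (
    azimuth_angles,
    best_fit_plane_normal,
    polar_angles,
    polar_to_stage,
    rotate_frame,
    wrapped_dtheta,
)
from .state import SimulationState


# ---------------------------------------------------------------------------
# individual metrics
# ---------------------------------------------------------------------------

def bond_tension(length: float, rest_length: float, k: float) -> float:
    """Signed spring tension k (L - r0): positive = tension, negative =
    compression."""
    return k * (length - rest_length)


def edge_tension_median(state: SimulationState, cfg: Config) -> float:
    """Median tension over the edge bonds (both endpoints margin)."""
    pairs, edge = state.bond_arrays()
    if not edge.any():
        return math.nan
    e = pairs[edge]
    lengths = np.linalg.norm(state.pos[e[:, 0]] - state.pos[e[:, 1]], axis=1)
    rest = state.cell_radius[e[:, 0]] + state.cell_radius[e[:, 1]]
    return float(np.median(cfg.harmonic_edge_spring_constant * (lengths - rest)))


def lopsidedness(margin_positions: np.ndarray) -> float:
    """Polar angle of the upward best-fit-plane normal, radians in [0, pi/2]."""
    normal = best_fit_plane_normal(margin_positions)
    return float(math.acos(max(-1.0, min(1.0, normal[2]))))


def straightness_index(ring_positions: np.ndarray) -> float:
    """Rotation-corrected SI of a closed margin path, in (0, 1].

    ``ring_positions`` must be in ring order.  The frame is first rotated so
    the ring's best-fit plane is horizontal (tilt correction), then segment
    lengths are sqrt(dphi^2 + dtheta^2) in the cylindrical (phi, theta)
    projection with wrapped azimuthal differences; SI = 2*pi / path length.
    """
    pts = np.asarray(ring_positions, dtype=float)
    normal = best_fit_plane_normal(pts)
    rotated = rotate_frame(pts, normal)
    phi = polar_angles(rotated)
    theta = azimuth_angles(rotated)
    dphi = np.roll(phi, -1) - phi
    dtheta = np.asarray(wrapped_dtheta(np.roll(theta, -1), theta))
    path = float(np.sum(np.sqrt(dphi**2 + dtheta**2)))
    return 2.0 * math.pi / path


# ---------------------------------------------------------------------------
# per-step record
# ---------------------------------------------------------------------------

@dataclass
class MetricsRecord:
    timestep: int
    time: float
    mean_phi: float
    stage: float
    margin_count: int
    edge_tension_median: float
    si: float
    lopsidedness: float
    cum_in: int
    cum_out: int
    cum_div: int
    n_cells: int


def measure(state: SimulationState, cfg: Config) -> MetricsRecord:
    ring = state.margin_ring()
    ring_pos = state.pos[ring]
    mean_phi = float(np.mean(polar_angles(ring_pos)))
    return MetricsRecord(
        timestep=state.timestep,
        time=state.time,
        mean_phi=mean_phi,
        stage=polar_to_stage(mean_phi),
        margin_count=len(ring),
        edge_tension_median=edge_tension_median(state, cfg),
        si=straightness_index(ring_pos),
        lopsidedness=lopsidedness(ring_pos),
        cum_in=state.cum_in,
        cum_out=state.cum_out,
        cum_div=state.cum_div,
        n_cells=state.n_cells,
    )


def records_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# derived series
# ---------------------------------------------------------------------------

def epiboly_speed(frame: pd.DataFrame, window: int = 11) -> pd.DataFrame:
    """Leading-edge speed (radians per time unit) vs position.

    Centered finite difference of mean_phi over time after a centered
    moving-average smooth (raw step-to-step differences are noise-dominated).
    """
    if len(frame) < 2:
        raise ValueError("need at least two records")
    phi = frame["mean_phi"].rolling(window, center=True, min_periods=1).mean()
    t = frame["time"].to_numpy()
    speed = np.gradient(phi.to_numpy(), t)
    return pd.DataFrame({"mean_phi": phi, "speed": speed, "time": t})


def aggregate_replicates(
    runs: list[pd.DataFrame],
    x: str,
    y: str,
    grid: np.ndarray | None = None,
    normalize_time: bool = False,
    n_grid: int = 200,
) -> pd.DataFrame:
    """Median and 5-95 percentile band of ``y`` across runs on a common grid.

    Each run is linearly interpolated onto the grid.  With
    ``normalize_time`` the x column is rescaled per run so its final sample
    is 1.0.  Raises if a run's x is not monotone non-decreasing.
    """
    if not runs:
        raise ValueError("need at least one run")
    xs, ys = [], []
    for frame in runs:
        xv = frame[x].to_numpy(dtype=float)
        if np.any(np.diff(xv) < 0):
            raise ValueError(f"x column {x!r} is not monotone within a run")
        if normalize_time:
            xv = xv / xv[-1]
        xs.append(xv)
        ys.append(frame[y].to_numpy(dtype=float))
    if grid is None:
        lo = max(v[0] for v in xs)
        hi = min(v[-1] for v in xs)
        grid = np.linspace(lo, hi, n_grid)
    resampled = np.vstack([np.interp(grid, xv, yv) for xv, yv in zip(xs, ys)])
    return pd.DataFrame(
        {
            "x": grid,
            "median": np.median(resampled, axis=0),
            "p5": np.percentile(resampled, 5, axis=0),
            "p95": np.percentile(resampled, 95, axis=0),
        }
    )
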