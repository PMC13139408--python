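"""Stochastic bond remodeling with an energy-gated acceptance criterion.

Once per event step every EVL cell is visited in fresh random order and
attempts one of four transformations, drawn uniformly from those available
to its type:

* internal cells — make a bond (to the nearest non-bonded cell) or break a
  randomly chosen bond;
* margin cells — additionally, leave the margin (its two margin neighbors
  bond directly) or hand margin status to a nearby internal cell bonded to
  both cells of an insertion site (the flanking edge bond is removed).

Candidates that survive the validity rules (minimum of 3 bonds per cell, at
most 3 margin bonds per internal cell, concavity for leaving, proximity for
joining) face a Metropolis-style gate: the bond-angle energy change
dE = lambda * (E_after - E_before), where each flanking angle contributes
(theta - theta_T)^2, is always accepted when dE <= 0 and with probability
exp(-dE) otherwise.  Target angles are 60 degrees inside the tissue
(hexagonal packing) and the regular-N-gon vertex angle pi - 2*pi/N along the
leading edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import Config
from .state import SimulationState

TARGET_INTERNAL = math.pi / 3.0


@dataclass
class RemodelEvent:
    type: str            # make_bond | break_bond | leave_margin | join_margin
    focal: int
    partner: int         # for leave/join: the re-typed cell's bond partner context
    delta_e: float
    accepted: bool


def target_angle(margin_count: int | None = None, edge: bool = False) -> float:
    """Preferred bond angle: pi/3 internally; the regular-N-gon vertex angle
    pi - 2*pi/N along the leading edge."""
    if not edge:
        return TARGET_INTERNAL
    if margin_count is None or margin_count < 3:
        raise ValueError("edge target angle needs a margin count >= 3")
    return math.pi - 2.0 * math.pi / margin_count


def bond_pair_energy(angles: list[float], theta_t: float) -> float:
    """Sum of squared deviations of flanking angles from the target."""
    return sum((a - theta_t) ** 2 for a in angles)


def accept(delta_e: float, rng: np.random.Generator) -> bool:
    """Metropolis-style gate: always accept dE <= 0, else with prob e^-dE."""
    if not math.isfinite(delta_e):
        raise ValueError("non-finite energy change")
    if delta_e <= 0.0:
        return True
    return rng.random() < math.exp(-delta_e)


# ---------------------------------------------------------------------------
# bond-angle energy change
# ---------------------------------------------------------------------------

def _tangent_basis(px: float, py: float, pz: float):
    """Orthonormal basis of the local tangent plane at a point on the sphere
    (scalar math: this sits on the per-visit hot path of the sweep)."""
    r = math.sqrt(px * px + py * py + pz * pz)
    rx, ry, rz = px / r, py / r, pz / r
    # e1 = normalize(z x rhat); fall back near the poles
    n = math.hypot(ry, rx)
    if n < 1e-9:
        h = math.hypot(rz, ry)
        e1x, e1y, e1z = 0.0, rz / h, -ry / h
    else:
        e1x, e1y, e1z = -ry / n, rx / n, 0.0
    e2x = ry * e1z - rz * e1y
    e2y = rz * e1x - rx * e1z
    e2z = rx * e1y - ry * e1x
    return (e1x, e1y, e1z), (e2x, e2y, e2z)


def _formation_terms(
    pos,
    c: int,
    p: int,
    existing: list[int],
    lam_internal: float,
    lam_edge: float,
    theta_t_edge: float,
    margin_unbonded,
    margin_bonded,
) -> float:
    """Energy change at endpoint ``c`` from inserting a bond to ``p``,
    given ``existing`` bonded neighbors (not including ``p``).

    The pair of adjacent neighbor bonds flanking the insertion direction is
    found by angular sort in the local tangent plane; angles themselves are
    measured between the 3D bond vectors.  Each angle term takes the target
    and lambda of its own context: the edge target and lambda when all three
    cells are margin cells in the configuration being scored (the two
    ``margin_*`` predicates give each configuration's cell types).

    ``pos`` is an indexable of (x, y, z) triples (a plain nested list on the
    sweep hot path)."""
    m = len(existing)
    if m < 2:
        return 0.0
    cx, cy, cz = pos[c]
    (e1x, e1y, e1z), (e2x, e2y, e2z) = _tangent_basis(cx, cy, cz)

    offs = []
    for j in existing:
        jx, jy, jz = pos[j]
        dx, dy, dz = jx - cx, jy - cy, jz - cz
        ang = math.atan2(
            dx * e2x + dy * e2y + dz * e2z, dx * e1x + dy * e1y + dz * e1z
        )
        offs.append((ang, j, dx, dy, dz))
    offs.sort()
    px_, py_, pz_ = pos[p]
    dpx, dpy, dpz = px_ - cx, py_ - cy, pz_ - cz
    ap = math.atan2(
        dpx * e2x + dpy * e2y + dpz * e2z, dpx * e1x + dpy * e1y + dpz * e1z
    )
    # cyclic flanking neighbors of the insertion direction
    idx = 0
    while idx < m and offs[idx][0] < ap:
        idx += 1
    _, a, ax, ay, az = offs[idx - 1]   # predecessor (wraps via index -1)
    _, b, bx, by, bz = offs[idx % m]   # successor

    na = math.sqrt(ax * ax + ay * ay + az * az)
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    npp = math.sqrt(dpx * dpx + dpy * dpy + dpz * dpz)

    def angle3d(ux, uy, uz, nu, vx, vy, vz, nv):
        d = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        return math.acos(max(-1.0, min(1.0, d)))

    def term(x: int, y: int, theta: float, margin_of) -> float:
        if margin_of(x) and margin_of(c) and margin_of(y):
            return lam_edge * (theta - theta_t_edge) ** 2
        return lam_internal * (theta - TARGET_INTERNAL) ** 2

    e_unbonded = term(a, b, angle3d(ax, ay, az, na, bx, by, bz, nb), margin_unbonded)
    e_bonded = term(
        a, p, angle3d(ax, ay, az, na, dpx, dpy, dpz, npp), margin_bonded
    ) + term(p, b, angle3d(dpx, dpy, dpz, npp, bx, by, bz, nb), margin_bonded)
    return e_bonded - e_unbonded


def bond_formation_delta_e(
    state: SimulationState,
    i: int,
    j: int,
    cfg: Config,
    margin_count: int,
    unbonded_override: dict[int, bool] | None = None,
    bonded_override: dict[int, bool] | None = None,
    bond_exists: bool = False,
    pos=None,
) -> float:
    """dE of forming bond (i, j); breaking is the exact negative.

    The two override dicts supply cell margin types in the configuration
    without and with the bond, for composite moves where a cell changes
    identity together with the bond change (a leaving margin cell is
    internal only once the bond between its neighbors exists; a joining
    internal cell is margin only once the flanking edge bond is gone).
    ``bond_exists`` evaluates the formation energy of an already-present
    bond (used to score breaking)."""

    def predicate(override: dict[int, bool] | None):
        ov = override or {}

        def margin_of(x: int) -> bool:
            if x in ov:
                return ov[x]
            return bool(state.is_margin[x])

        return margin_of

    margin_unbonded = predicate(unbonded_override)
    margin_bonded = predicate(bonded_override)
    theta_t_edge = target_angle(margin_count, edge=True)
    if pos is None:
        pos = state.pos.tolist()
    de = 0.0
    for c, p in ((i, j), (j, i)):
        existing = [n for n in state.adjacency[c] if n != p] if bond_exists else \
            list(state.adjacency[c])
        de += _formation_terms(
            pos, c, p, existing,
            cfg.lambda_bond_angle, cfg.lambda_edge_bond_angle,
            theta_t_edge, margin_unbonded, margin_bonded,
        )
    return de


# ---------------------------------------------------------------------------
# the per-timestep sweep
# ---------------------------------------------------------------------------

def remodel_sweep(
    state: SimulationState,
    cfg: Config,
    rng: np.random.Generator,
) -> list[RemodelEvent]:
    """Visit every EVL cell once in random order; attempt one transformation
    each.  Returns the events that reached the acceptance gate (valid
    candidates), with their outcomes.  Positions never change during the
    sweep; only connectivity and margin identity do."""
    events: list[RemodelEvent] = []
    n = state.n_cells
    order = rng.permutation(n)
    margin_count = int(state.is_margin.sum())
    tree = cKDTree(state.pos)
    adjacency = state.adjacency
    is_margin = state.is_margin
    margin_list = is_margin.tolist()
    min_bonds = cfg.min_bonds
    max_mb = cfg.max_margin_bonds_per_internal
    pos_list = state.pos.tolist()

    def mbc(x: int) -> int:
        return sum(1 for y in adjacency[x] if margin_list[y])
    # polar angles for the concavity test, fixed for the sweep
    rsq = np.linalg.norm(state.pos, axis=1)
    cos_phi = (state.pos[:, 2] / rsq).tolist()
    # one uniform draw per visit selects the move (2-way or 4-way by type)
    move_draws = rng.random(n)

    def dist(a: int, b: int) -> float:
        xa, ya, za = pos_list[a]
        xb, yb, zb = pos_list[b]
        return math.sqrt((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2)

    for t, c in enumerate(order):
        c = int(c)
        if margin_list[c]:
            move = int(move_draws[t] * 4.0)
        else:
            move = int(move_draws[t] * 2.0)

        if move == 0:  # ---- make_bond -------------------------------------
            radius = cfg.bond_search_factor * 2.0 * float(state.cell_radius[c])
            cand = tree.query_ball_point(state.pos[c], radius)
            best = -1
            best_d = math.inf
            focal_margin = margin_list[c]
            for j in cand:
                if j == c or j in adjacency[c]:
                    continue
                if focal_margin and margin_list[j]:
                    continue  # margin-margin bonds change only via leave/join
                dd = dist(c, j)
                if dd < best_d or (dd == best_d and j < best):
                    best_d = dd
                    best = int(j)
            if best < 0:
                continue
            j = best
            # margin-bond ceiling on whichever endpoint is internal
            if focal_margin and not margin_list[j]:
                if mbc(j) + 1 > max_mb:
                    continue
            elif not focal_margin and margin_list[j]:
                if mbc(c) + 1 > max_mb:
                    continue
            de = bond_formation_delta_e(state, c, j, cfg, margin_count, pos=pos_list)
            ok = accept(de, rng)
            events.append(RemodelEvent("make_bond", c, j, de, ok))
            if ok:
                state.add_bond(c, j)

        elif move == 1:  # ---- break_bond ----------------------------------
            if margin_list[c]:
                candidates = [j for j in adjacency[c] if not margin_list[j]]
            else:
                candidates = list(adjacency[c])
            if not candidates:
                continue
            j = int(candidates[int(rng.integers(len(candidates)))])
            if len(adjacency[c]) - 1 < min_bonds or len(adjacency[j]) - 1 < min_bonds:
                continue
            de = -bond_formation_delta_e(
                state, c, j, cfg, margin_count, bond_exists=True, pos=pos_list
            )
            ok = accept(de, rng)
            events.append(RemodelEvent("break_bond", c, j, de, ok))
            if ok:
                state.remove_bond(c, j)

        elif move == 2:  # ---- leave_margin --------------------------------
            m = [j for j in adjacency[c] if margin_list[j]]
            if len(m) != 2:
                continue  # corrupted locally; skip rather than crash mid-sweep
            m1, m2 = m
            # valid only where the edge is unambiguously concave: the focal
            # cell strictly closer to the animal pole than both neighbors
            if not (cos_phi[c] > cos_phi[m1] and cos_phi[c] > cos_phi[m2]):
                continue
            if m2 in adjacency[m1]:
                continue
            de = bond_formation_delta_e(
                state, m1, m2, cfg, margin_count, bonded_override={c: False},
                pos=pos_list,
            )
            ok = accept(de, rng)
            events.append(RemodelEvent("leave_margin", c, -1, de, ok))
            if ok:
                state.add_bond(m1, m2)
                is_margin[c] = False
                margin_list[c] = False
                state.cum_out += 1
                margin_count -= 1

        else:  # ---- join_margin -------------------------------------------
            m = [j for j in adjacency[c] if margin_list[j]]
            if len(m) != 2:
                continue
            sides = [m[0], m[1]] if rng.random() < 0.5 else [m[1], m[0]]
            chosen = -1
            partner_m = -1
            for mm in sides:
                shared = [
                    j for j in adjacency[c] & adjacency[mm] if not margin_list[j]
                ]
                if not shared:
                    continue
                # nearest by summed distance to the two margin cells
                best_j, best_s = -1, math.inf
                for j in shared:
                    s = dist(j, c) + dist(j, mm)
                    if s < best_s or (s == best_s and j < best_j):
                        best_s, best_j = s, j
                j = best_j
                # proximity: within join_distance_factor mean cell diameters
                # of the vegetally-farther margin cell of the site
                veg = c if cos_phi[c] < cos_phi[mm] else mm
                diam = (2.0 / 3.0) * float(
                    state.cell_radius[c] + state.cell_radius[mm] + state.cell_radius[j]
                )
                if dist(j, veg) > cfg.join_distance_factor * diam:
                    continue
                # must hold no margin bonds besides the insertion site
                if mbc(j) != 2:
                    continue
                chosen, partner_m = j, mm
                break
            if chosen < 0:
                continue
            j, mm = chosen, partner_m
            de = -bond_formation_delta_e(
                state, c, mm, cfg, margin_count,
                unbonded_override={j: True}, bond_exists=True, pos=pos_list,
            )
            ok = accept(de, rng)
            events.append(RemodelEvent("join_margin", j, -1, de, ok))
            if ok:
                state.remove_bond(c, mm)
                is_margin[j] = True
                margin_list[j] = True
                state.cum_in += 1
                margin_count += 1
                # enforce the margin-bond ceiling on the new margin cell's
                # internal neighbors
                for x in list(adjacency[j]):
                    if not margin_list[x] and mbc(x) > max_mb:
                        state.remove_bond(j, x)
    return events
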