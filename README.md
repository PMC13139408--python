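# epiboly

An agent-based, center-based simulator of zebrafish **epiboly** — the
spreading of the enveloping layer (EVL), the embryo's outer squamous
epithelium, from a cap over the animal pole of the yolk cell to complete
engulfment.  The package is for developmental biophysicists who want a
cell-resolution model of a passively stretched epithelium: how exogenous
forces applied at the leading edge propagate through cell–cell adhesions,
how the tissue rearranges internally without tearing, and how the advance
of the margin stays synchronized.

## The model in brief

Each EVL cell is a particle at its center of mass with a cell radius `r`;
the yolk (plus deep cells) is one immobile sphere.  Dynamics are
overdamped, `dx = (F/gamma) dt`.  Pairwise forces are ideal springs with
rest length `r_i + r_j`: attract-only on bonded pairs (adhesion),
repel-only on all close pairs (volume exclusion), plus a containment
spring to the yolk center.  An exogenous force `F_i = F * L_i` pulls each
margin cell along the meridian toward the vegetal pole, where `L_i` is the
cell's azimuthal share of the edge; with **force regulation** (Model 2)
the shares are reweighted by `(pi - phi_i)` so lagging cells are pulled
harder — a negative feedback that keeps the edge centered on the pole.

Cell rearrangement comes from **stochastic bond remodeling**: each step,
every cell attempts to make or break one bond (margin cells can also leave
the margin or recruit an internal cell into it).  Candidate moves are
gated by a bond-angle energy,

    dE = lambda * sum (theta - theta_T)^2 ,    P(accept) = min(1, e^-dE),

with target angles `theta_T = 60°` inside the tissue (hexagonal packing)
and `180° - 360°/N` along the N-cell leading edge.  Cell division is a
Poisson process calibrated so ~412 divisions accrue by 55% epiboly, each
daughter taking `sqrt(2)/2` of the parent's radius and drag.  Stage is
measured by the mean margin polar angle `phi` (percent-epiboly
`p = (1 - cos phi)/2`); the leading edge is scored by its median bond
tension, its *lopsidedness* (tilt of the best-fit margin plane) and its
*straightness index* `SI = 2*pi / path length` in a tilt-corrected
(phi, theta) projection.

## Worked example

```bash
epiboly run --seed 1 --out runs/m2_seed1
```

runs a full Model 2 simulation (force regulation, remodeling, and division
enabled, all defaults) from initialization at 43% epiboly to termination at
`mean phi = 0.95*pi` and prints

```
completed at step 1645: mean_phi=2.985 rad, SI=0.780, lopsidedness=0.0138 pi
```

i.e. the margin closed on the vegetal pole (2.985 rad = 0.95*pi, ~99%
epiboly) with a near-straight leading edge and a best-fit margin plane
tilted well under 0.1*pi.  `runs/m2_seed1/metrics.csv` holds one row per
timestep (stage, margin count, edge tension, SI, lopsidedness, cumulative
in/out migrations and divisions), `events.csv` the accepted remodeling and
division events, and `final_state/` the cells/bonds snapshot with its JSON
manifest.  The same library surface is available in Python:

```python
import epiboly as ep
traj = ep.run(ep.Config(seed=1))
traj.metrics[["mean_phi", "margin_count", "si", "lopsidedness"]].tail()
```

Other subcommands: `epiboly init` (starting state only), `recoil` (cut the
driving force near the end of epiboly, with or without remodeling),
`lineage` (permanent labels on the margin, an internal tier, or a patch),
`sweep` (replicated parameter sweeps, e.g. `--param lambda_global
--values 3,4,5,6,10`), `aggregate` (median + 5–95% bands across runs) and
`plot`.

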