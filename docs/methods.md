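# Model and methods

## The model

The package simulates the spreading (epiboly) of the zebrafish enveloping
layer (EVL) — the squamous epithelial monolayer that crawls over the yolk
cell from a polar cap to full engulfment — as a center-based agent model.
Each EVL cell is a point at its center of mass with an assigned *cell
radius* (the target apical radius; bonds and volume exclusion are built on
it) and a smaller *particle radius* (used only for containment against the
yolk surface and for rendering).  The yolk plus deep-cell mass is a single
immobile sphere at the origin; the animal pole is on +z.  All motion is
overdamped: displacement per step is force divided by a drag coefficient
("mass" in the center-based framework) times dt.

Three standing force classes act on cells:

* **Adhesion** — attract-only harmonic springs on explicitly bonded pairs,
  rest length equal to the sum of the two cell radii, spring constant
  `harmonic_spring_constant` (0.5) or `harmonic_edge_spring_constant` (0.5)
  when both endpoints are margin cells.
* **Volume exclusion** — repel-only harmonic springs between *every* close
  EVL pair, bonded or not (`harmonic_repulsion_spring_constant`, 0.5), with
  the same rest length.  A bonded pair therefore feels exactly one full
  spring; repulsion is not double-counted.
* **Containment** — a full harmonic spring between each cell and the yolk
  center with rest length yolk-particle-radius + EVL-particle-radius
  (3.0 + 0.09) and constant `harmonic_yolk_evl_spring_constant` (4.0),
  holding the monolayer on the spherical surface.

The exogenous epiboly force acts only on margin (leading-edge) cells, along
the local meridian tangent toward the vegetal pole.  Each margin cell's
share of the edge is `L_i`, half the azimuthal (wrapped, signed) angular
distance to each of its two ring neighbors, summed; sum(L_i) = 2*pi exactly.
Model 1 applies `F_i = F * L_i` with `F = force_per_unit_length = 0.7`.
Model 2 (force regulation) computes raw weights `W_i = L_i * (pi - phi_i)`
— lagging cells, with smaller polar angle, get proportionally more — and
rescales them to sum to the leading-edge circumference at the mean margin
polar angle, `2*pi*R*sin(mean phi)` with `R = 3.09` the EVL mid-surface
radius.  During development we also evaluated normalizing to the
circumference in the same angular units as `L_i` (radius 1); that variant
is unstable — runs go lopsided after the margin passes ~0.66*pi and the
ring slides off the pole — so the mid-surface-radius normalization is the
one shipped.

## Bond remodeling

Once per event step, every cell is visited in fresh random order and draws
one transformation uniformly from those available to its type: internal
cells make or break a bond; margin cells can additionally leave the margin
(their two ring neighbors bond directly) or recruit a nearby internal cell
into the margin (the flanking edge bond is deleted).  Validity rules: every
cell keeps at least 3 bonds; an internal cell holds at most 3 bonds to
margin cells; a margin cell may leave only where the edge is unambiguously
concave (it is strictly closer to the animal pole than both ring
neighbors); a joining cell must be bonded to both cells of the insertion
site, hold no other margin bonds, and lie within 0.75 mean cell diameters
of the vegetally-farther flanking cell.  Surviving candidates pass a
Metropolis-style gate on the bond-angle energy change: each angle between
adjacent bonds at the two endpoints contributes
`lambda * (theta - theta_T)^2`, with `theta_T = 60 degrees`
(`lambda_bond_angle = 3.75`) inside the tissue and the regular-N-gon vertex
angle `180 - 360/N degrees` (`lambda_edge_bond_angle = 4.0`, N the current
margin count) for angles between three consecutive margin cells.  A move
with `dE <= 0` is always accepted, otherwise with probability `exp(-dE)`.
Formation and breaking of the same bond have exactly opposite energies.

Numerical details that the energy needs but no formula fixes: the pair of
bonds flanking a candidate bond is found by angular sort of the bonded
neighbors in the local tangent plane; the angles themselves are measured
between the 3D bond vectors (the sheet is locally flat at cell scale, so
these agree with tangent-plane angles to high order).  For composite moves
(leave/join) each angle term is classified edge-vs-internal using the cell
types of the configuration being scored: a leaving cell counts as internal
in the bonded (post-move) configuration and as margin in the unbonded one,
and symmetrically for a joining cell.  Scoring both configurations with a
single type assignment is qualitatively wrong in both directions — all-pre
typing forbids every leave, all-post typing accepts essentially all of them
and the margin collapses within a hundred steps.

## Cell division

A per-area division rate is fixed at run start:
`total_epiboly_divisions / (cap area at 55% epiboly - cap area at the run's
actual starting stage)`, cap areas on the mid-surface sphere
(`A(p) = 4*pi*R^2*p`).  Each step the expected count is the rate times the
increase of cap area beyond its running maximum (measuring against the
running maximum rather than the previous step keeps fluctuations of the
mean margin angle from rectifying into spurious divisions), and the
realized count is Poisson.  Division ceases at 55% epiboly; each cell
divides at most once.  Daughters take cell radius and drag scaled by
sqrt(2)/2 (half the apical area at constant epithelial thickness; drag
scales with circumference), centers offset by half a daughter radius along
the division axis — a uniformly random in-sheet direction for internal
cells, the horizontal azimuthal direction for margin cells, whose daughters
are both margin and inserted adjacently in the ring.  The new daughter is
bonded to at least three nearest neighbors by the initializer's rule.

## Initialization

The target cell radius tiles the starting cap:
`r = 2R * sqrt(p/n)` with `p = epiboly_initial_percentage = 0.43` (the
measured leading-edge position of the stage conventionally called "30%
epiboly") and `n = 660`.  The whole sphere is over-filled with `n/p` cells
placed uniformly at random, relaxed under repulsion + containment until the
mean per-step displacement falls below 1e-4 distance units, bonded to
nearest neighbors until every cell has at least 5 bonds (distance cap 2.5x
the rest length), relaxed again briefly, and trimmed: cells vegetal of the
starting latitude are deleted, the kept cells bonded to a deleted one (the
graph boundary of the kept subset) become the margin, and margin-margin
bonds are rebuilt as a single ring in azimuthal order.  A repair pass
restores the minimum bond count and the margin-bond ceiling.  The surviving
count is stochastic around 660 (empirically ~657 +/- 19 over seeds) and the
initial margin straightness index is ~0.9.

## Metrics

* **Stage**: mean polar angle of the margin cells; percent-epiboly
  `p = (1 - cos phi)/2`.
* **Edge tension**: median over edge bonds of `k (L - r0)` (positive =
  tension).
* **Lopsidedness**: polar angle of the upward normal of the best-fit plane
  (SVD of centered coordinates) through the margin positions.
* **Straightness index (SI)**: the frame is rotated so the margin best-fit
  plane is horizontal, positions are mapped to (phi, theta), and SI is
  2*pi divided by the ring path length with segments
  `sqrt(dphi^2 + dtheta^2)` and azimuthal differences wrapped to the
  shortest branch (any other seam choice breaks rotation invariance).
* **Speed**: gradient of the mean margin angle against time after a
  centered 11-sample moving average (raw differences are noise-dominated).
* **Replicate aggregation**: linear interpolation of each run onto a common
  grid (normalized time maps each run's final step to 1.0), then per-point
  median and 5th/95th percentiles with linear percentile interpolation.

## Integration, pacing, and termination

The explicit overdamped update is stable for
`dt * k_max / drag_min << 2`; the default `dt = 0.025` has ratio 0.14.
Because the remodeling cadence is fixed at one sweep per cell per event
step, dt also sets how much strain accumulates between sweeps; at the
default, full Model 2 runs terminate after roughly 1,700–2,200 event steps,
the same order as the few-thousand-step runs the model is calibrated
against.  Runs terminate when the mean margin polar angle reaches
`0.95*pi` (~99% epiboly).  Without force regulation the margin typically
develops a vegetal protrusion instead of closing uniformly; those runs
additionally stop when any single margin cell passes `0.98*pi`.  A step cap
(default 50,000) bounds stalled runs, e.g. under a strong bond-angle
constraint (global lambda >= 6), where expansion asymptotes short of the
termination angle.

## Experiment protocols

* **Recoil**: run to a trigger angle (default `0.9*pi`, ~97.5% epiboly),
  then phase 1 disables both the exogenous forces and remodeling
  (instantaneous elastic response), and phase 2 re-enables remodeling with
  forces still off (long-term response).  The reorganized tissue shows a
  small recoil that plateaus, then a much larger contraction once
  remodeling resumes — the viscoelastoplastic signature.
* **Elastic control**: with remodeling disabled from the start the sheet is
  purely elastic.  Under the uniform edge force it creeps toward an elastic
  equilibrium near a mean angle of ~0.69*pi rather than engulfing (the
  fixed topology cannot shorten the edge), so the control protocol pulls
  for a fixed step budget and then releases; most of the deformation
  springs back, and the edge SI falls monotonically during the pull.
* **Lineage labeling**: permanent labels on the margin ring, on the k-th
  internal tier (graph distance k from the ring), or on an angular patch
  (default 30 x 15 degrees) adjacent to the margin.
* **Sweeps**: replicated runs over values of the global bond-angle
  constraint, the edge-only constraint, or the edge spring constant (the
  purse-string variant is Model 1 with a raised edge spring constant),
  aggregated with the replicate machinery above.

## What the simulations do and do not show

All data in this package are generated by the model itself; no biological
measurements are consumed.  Agreement with the published benchmarks
(staging arithmetic, division calibration, initial straightness, margin
loss, the Model 1 vs Model 2 synchrony contrast) therefore validates the
re-implementation of the model, not the biology.  Known quantitative
limitations of this implementation, at the default parameters:

* Model 2 runs are synchronous in the qualitative sense (the margin closes
  on the pole; final lopsidedness is far below Model 1's) but mid-to-late
  run excursions of the lopsidedness metric reach ~0.04–0.08*pi across
  seeds, above the ~0.03*pi ceiling reported for the original.  The
  excursions correlate with the margin ring thinning earlier than in the
  original (out-migration concentrates in the initial straightening burst),
  which makes the discrete per-cell force shares noisier; they are damped
  and reversed by the force regulation rather than running away.
* The net margin loss (~50 cells median) sits at the low edge of the
  reported ~60, for the same reason.
* The margin straightness index rises from ~0.91 at initialization to a
  peak of ~0.97 but does so mostly in the first tenth of the run, and in
  seeds with large lopsidedness excursions it sags mid-run before
  recovering — a compressed version of the original's steady climb to
  ~1.0.
* In the two-phase recoil experiment the first phase reproduces the
  published signature (minimal instantaneous recoil, then a plateau), but
  on re-enabling remodeling our margin resumes *closing* on the pole —
  circumferential hoop tension outcompetes the meridional pull of the
  stretched sheet once plasticity returns — where the original contracts
  back toward the animal pole.  New bonds form between nearest unbonded
  neighbors at near-rest length, so interior tension relaxes in place
  rather than by bulk contraction; this plastic-relief pathway appears
  stronger here than in the original.
* In-migration to the margin is rare (a handful of events per run), which
  matches the original's description of occasional inward movement.

Problem sizes in the test-suite and acceptance runs (20 initializations;
5 replicates per model variant; a 1,000-step invariant run; capped elastic
and stall runs) are the package's own choice of replication, selected to
exercise every protocol at full model size.  Model 1 replicates are bounded
at 4,000 event steps: the quantity they are scored on — the pre-distortion
straightness peak — is reached by step ~2,700 at the latest across seeds,
while the protrusion stop can wander out past step 6,000.
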