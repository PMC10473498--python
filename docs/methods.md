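# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not demonstrate.

## Boundary extraction

Segmentation masks are binarised (any nonzero pixel is foreground), their
8-connected components labelled, and the outer contour of each component
with at least `min_pixels` (default 50) pixels traced with marching squares
at the 0.5 iso-level, giving half-pixel resolution. Interior holes are
ignored. Coordinates are continuous with x right / y up; a pixel at row r,
column c maps to (c, nrows − 1 − r).

Simulated organoids are handled differently: the epithelial monolayer is a
closed self-avoiding chain of cells, so the shortest closed tour through
the cell centres recovers the boundary without any segmentation. The tour
search is an order-encoded genetic algorithm — nearest-neighbour tours from
several random starts plus random permutations, tournament selection, order
crossover, segment-reversal mutation, single-individual elitism, and
periodic 2-opt polishing of the incumbent (defaults: population 24, 60
generations). On the few-hundred-point clouds the simulator produces, this
reliably reaches hull-order tours; it is deterministic given the seed.

## Elliptic-Fourier boundary representation

The counting pipeline needs curvature, and raw contours are too rough to
differentiate. Closed boundaries are therefore expanded in elliptic Fourier
descriptors on the arc-length parametrisation: per-harmonic coefficients
(aₙ, bₙ, cₙ, dₙ) are the exact Fourier integrals of the piecewise-linear
contour, the DC term is the exact path mean, and the period is the polygon
perimeter. Truncation at H harmonics low-pass filters the outline, so H is
the resolution parameter of the whole method: small H keeps only the gross
body, large H keeps individual buds (and, eventually, pixel noise).
Curvature and outward normals come from the analytic series derivatives,

    kappa = (x'y'' − y'x'') / (x'² + y'²)^{3/2},

with the ccw convention that convex arcs have kappa > 0. Curves are sampled
at max(512, 16·H) uniform parameter values — enough to resolve the highest
harmonic — and a vanishing-speed sample raises an error rather than
returning garbage curvature.

Trained harmonic counts may be fractional (averages over optimisation
runs); they are rounded to the nearest integer whenever applied.

## Crypt counting

Concave boundary regions (maximal runs with kappa < −kappa_tol,
wrap-around handled; kappa_tol defaults to 0 because the Fourier truncation
already suppresses noise) mark the "necks" between buds. The boundary
segment between two cyclically adjacent concave-region midpoints, closed by
the chord joining them, is one candidate crypt region — so k ≥ 2 necks
yield exactly k candidates that tile the boundary, and fewer than 2 necks
yield none (a spheroid counts zero). Each candidate is scored by two
dimensionless descriptors,

    area_norm   = |segment + chord area| / organoid area,
    arclen_norm = segment arc length / boundary arc length,

and accepted iff min_area ≤ area_norm ≤ max_area and arclen_norm ≥
min_arclen (bounds inclusive; ties accept). Normalisation makes the
classifier scale-free; the area window rejects noise wiggles and
villus-scale bulk, the arc-length floor rejects sharp corners. Circularity
(4πA/P²) is reported from the Fourier-smoothed curve: the raw
marching-squares contour carries a resolution-independent staircase
perimeter inflation of several percent that would bias it low (the raw
value remains available via `circularity(poly)` on the traced polygon).

The chord-closed candidate construction is the package's central
interpretive choice: it makes each budding lobe one well-defined region
with computable area and arc length.

## Training

Parameters (harmonics, min/max area, min arc length) are fitted per culture
day by minimising the mean percentage error |hand − code| / hand × 100
against manual counts, averaged per organoid. The objective is piecewise
constant with plateaus, so the optimiser is simulated annealing: Gaussian
proposals with standard deviation 10% of each parameter's bound range,
clipped to bounds (defaults: harmonics [3, 40], areas [0.001, 0.6], arc
length [0, 0.3]); geometric cooling from an initial temperature equal to
the objective spread over 20 random probes down to 10⁻³ of it across the
budget (default 300 iterations); Metropolis acceptance; best-seen
parameters returned, so the result is never worse than the starting point.
Harmonics are optimised as a continuous variable and rounded inside the
objective. Proposals with min_area ≥ max_area are rejected as infeasible.

## Agent-based organoid model

The simulator is a 2D off-lattice cell-centre model of an organoid
cross-section, re-specified from its published description rather than
ported from any existing code. A closed ring of epithelial cells (initial
length 20; ring radius 20/2π CD) is embedded in a unit-spacing hexagonal
mesh of non-cellular nodes: Matrigel outside the ring, lumen inside, with
the outermost lattice rim pinned. All distances are in cell diameters (CD)
and times in hours; forces are in an arbitrary unit that cancels against
the drag coefficient.

Mechanics. Nodes connected by Delaunay edges (pruned beyond a 1.5 CD
cut-off) interact by linear springs, force k·(d − s) along the pair axis
with k = 15 and rest length s = 1 (growing 0.1 → 1 over the first hour for
newborn sibling pairs); mixed-stiffness pairs use the arithmetic mean of
the endpoint multipliers (1 for soft cells and both media, 4.5 for hard
cells). Every epithelial cell with exactly two epithelial neighbours feels
a basement-membrane restoring force β·(κ₀ − κ_local) along its outward
normal, with β = 10 and target curvature κ₀ = 0.2 CD⁻¹; κ_local is the
signed circumcircle curvature through the cell and its two neighbours. The
outward side is determined by walking the epithelial chain and orienting
each closed cycle ccw — a centroid-based heuristic fails inside folded
buds, where "outward" locally points toward the organoid centre. Motion is
overdamped forward Euler, x ← x + (F/η)·Δt with η = 1 and Δt = 0.005 h; a
step that moves any node more than 1 CD raises an instability error.

Proliferation. Cycles are G1 ~ U(12, 14) h plus a fixed 10 h (22–24 h
total); each initial cell starts at a uniformly random phase so divisions
desynchronise. A dividing cell is replaced by daughters ±0.05 CD along a
random axis; the first keeps the parent type. In the two-type (original)
variant every cell divides forever and the second daughter is soft with
probability p = 0.2. In the four-type (proposed) variant stem cells divide
into {SC 0.89, PC 0.09, TA 0.02} and transit-amplifying cells into
{TA 0.90, EC 0.10} before the global 120 h switch and {TA 0.70, EC 0.30}
after it; PC and EC never divide. Initial proportions are SC/TA/PC =
0.42/0.49/0.09 (proposed) or soft/hard = 0.2/0.8 (original).

Anoikis and monolayer maintenance. A monolayer cell touches epithelium
along the ring, Matrigel on its outer side and lumen on its inner side.
Losing all epithelial contact removes a cell immediately. Losing a medium
contact — no Matrigel edge means the cell was shed inward into the lumen;
no lumen edge that it was expelled outward into the Matrigel — starts a
per-cell detachment clock, and only sustained loss (2 h by default, the
``detachment_time``) is fatal. The persistence window separates real
expulsion from the transient geometric shadowing that every division
causes while the newborn pair is pulled into line; newborns additionally
get a one-hour grace matching the pair-spring maturation time. Together
these rules keep the epithelium single-file: surplus daughters are culled
instead of stacking into a solid mass.

Fluid media. Both non-cellular media are managed as constant-density
fluids at connectivity rebuilds: lumen edges stretched beyond 1.8 CD (from
the raw triangulation, up to 3.5 CD) are split by inserting a lumen node
at the midpoint, and any non-pinned medium node squeezed below 0.55 CD of
a neighbour is deleted. Insertion keeps the lumen supporting the monolayer
and filling expanding buds as the organoid inflates (without it the medium
dilutes and buds collapse into single-file finger chains); deletion lets
the media yield under the pressure of a growing ring.

Numerics. Full Delaunay rebuilds (with the anoikis pass) happen every
0.1 h; between rebuilds, over-cutoff edges are severed each step and
newborn cells are connected locally (pair spring plus the parent's
neighbourhood) until the next rebuild. Displacements per 0.1 h are far
below one cell diameter, so connectivity is quasi-static between rebuilds;
halving the rebuild period does not measurably change the micro-oracle
results. Event order within a step: move → reconnect/cull → divide.

## Synthetic fixtures

The lobed-shape generator emulates the one feature of organoid
cross-sections the counter cares about — a convex body with k finger-like
buds separated by narrow concave necks — as a radial profile that sits on a
plateau (base_radius + lobe_length) and dips smoothly to base_radius at k
evenly spaced necks of controllable arc width. By construction a
zero-jitter k-lobed fixture has exactly k concave regions, so ground truth
is exact for k = 0…8. Planted-parameter training sets draw fixture
geometry at random within safe ranges and re-draw any fixture the planted
classifier mis-scores (bounded retries), guaranteeing a zero-error optimum
exists; annealing recovery is then measured against that known optimum.

What the fixtures do not emulate: segmentation noise beyond uniform radial
jitter, touching/overlapping organoids, intensity-dependent mask defects,
or out-of-focus boundary loss. Passing the fixture suites therefore
demonstrates the geometry and optimisation machinery, not robustness to
real microscope segmentation artefacts.

## Study conditions and problem sizes

The in-silico study runs the simulator to 168 h with snapshots at 72, 120
and 168 h (days 3/5/7), orders each snapshot's epithelial centres with the
GA-TSP, and counts crypts with the published in-silico day parameters
(H = 13/27/24, area windows and arc-length floors per day). The package's
reference script uses 20 replicates per model variant, which puts the
standard error of the mean crypt count near the published per-50-replicate
values while keeping a full rerun at desk scale.

## Known limitations

* The mechanical model is a re-specification from a prose description: the
  basement-membrane force law, lumen handling and anoikis
  operationalisation are this package's documented interpretations, so
  only distribution-level agreement with the reference simulated
  morphometrics can be expected, not trajectory-level equivalence.
* Simulated rings grow slowly under these rules (division-driven insertion
  barely outruns culling), so early-day organoids are small and their buds
  large relative to the body. Day-7 mean crypt counts of both variants land
  on the published values, but the day-3 count runs high, the day-5 count
  low (the published day-5 area window accepts only buds below ~2% of
  organoid area, smaller than the buds a few-dozen-cell ring can carry),
  and day-3 circularity slightly high. Because the trajectory of events —
  reconnection, media refill/yield, anoikis — is event-driven, simulated
  paths are not continuous in the timestep; integrator convergence is
  checked on frozen connectivity instead.
* Simulated organoids here are a few dozen to ~100 cells by day 7; their
  boundary polygons are coarser than segmented-image contours, which makes
  high-harmonic fits (day-5/7 parameter sets) sensitive to single-cell
  surface bumps.
* The counter assumes one closed outer boundary per organoid; touching
  organoids must be separated at segmentation time.
* Training recovers parameter sets that reproduce counts, not unique
  parameters: the objective has broad zero-error plateaus by design.
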