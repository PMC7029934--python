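# Methods

## Domain and coordinate convention

All rasters share one convention: streamwise index *i* runs from 0 at the
**upstream** edge (the success line) to *n* − 1 at the **downstream** edge
(where agents enter); spanwise index *j* runs 0 … *m* − 1; cell centroids sit
at ((i + 0.5) Δ, (j + 0.5) Δ) with Δ the cell size (default 0.5 mm, the
scale at which a single cell approximates an elver's body cross-section).
Water flows in +i, elvers ascend in −i. Velocity is stored as the scalar
magnitude of the time-averaged flow on a plane 3 mm above the tile bed;
vector fields are reduced to magnitude on ingest, because both models
difference scalar speeds. Dry cells (stud cross-sections, walls) are nodata,
serialised with a −1 sentinel, which can never collide with a physical speed.

`temporal_average` marks a cell nodata if *any* selected snapshot is dry
there: a sometimes-dry cell has no well-defined time-averaged swimming
environment. `mirror_spanwise` rebuilds a full-width domain from a
half-domain computed under a symmetry boundary.

## Burst-speed model

Swimming-performance tables give, per body length, the 10th/50th/90th
percentile burst speed — the anaerobic sprint capability conventionally
sustainable for T = 20 s in total. The IBM needs a sampling distribution, so
the triple is inverted to a lognormal:

    mu = ln q50,        sigma = (ln q90 - ln q10) / (2 z0.9),   z0.9 = 1.28155

Three quantiles over-determine two parameters. We pin μ to the median (the
central speed the classification threshold also uses) and take σ as the mean
of the two one-sided estimates — exact for log-symmetric triples,
least-squares over the two tail residuals otherwise. "Lognormal" here means
the distribution fitted by inverting its quantile function, not the
inverse-Gaussian family. Percentile speeds at untabulated lengths are linear
interpolations; extrapolation outside the table is refused rather than
guessed. The packaged table is synthetic (median ≈ 5 body lengths/s, fixed
tail ratios) and exists only so the pipeline runs end-to-end; it must be
replaced with measured data for any biological conclusion.

## Classification and connectivity

A cell is passable when u < v (strict), impassable when u ≥ v: an elver
exactly at its burst speed makes no headway, so the tie goes to impassable.
Passability is therefore monotone in v — raising the threshold can only grow
the passable set.

Path existence uses the same first-order Moore adjacency as agent movement,
so "a passable route exists" is exactly "an automaton could in principle
ascend". One subtlety: agents spawn on any *wetted* downstream-edge cell,
including impassable ones, and may step off them onto a passable neighbour.
The connectivity search therefore seeds with passable downstream-edge cells
*plus* passable Moore-neighbours of wetted edge cells; without this, rare
grids exist where an automaton passes although the edge-row-only search says
no path. The fast boolean check labels connected components
(`scipy.ndimage.label`); a breadth-first search produces a witness path.

## Movement engine

Both models share one mechanic per move: partition the ≤ 8 Moore neighbours
into upstream (3), cross-stream (2) and downstream (3) groups; delete
non-viable cells; draw uniformly from the highest-priority non-empty group
(upstream first normally, downstream first when falling back); if all groups
are empty, hold — the move still counts. Diagonal moves cover Δ√2
(Euclidean centroid distance; a switch allows ×1 for sensitivity studies).

**Stuck / fall-back.** After every move (once the trailing window is full),
a normal-mode agent whose net upstream progress over the last 20 moves is
≤ 2 cells becomes stuck and falls back for exactly 30 moves; during
fall-back the assessment is suspended and on exit the window buffer resets,
preventing an immediate re-trigger before the agent can re-route. Net
displacement (not gross path length) is used because oscillation in a
cul-de-sac — the pathology the rule exists for — covers arbitrary gross
distance while gaining nothing. The window is assessed as rolling; a
disjoint-block variant is available via `stuck_assessment="block"`. An agent
forced toward the entrance simply cannot leave the grid: off-grid neighbours
are never candidates, so the cohort size is conserved. Defaults
(1000 agents, 10 000 timesteps, 20/2/30) are the sensitivity-analysed
operating point of the original study design.

**Per-agent viability and time (IBM).** A destination is viable for an
upstream/cross move iff v − u(dest) > 0 (per-agent classification at
threshold v); downstream moves need only water. Move times are
d/(v − u) upstream/cross and d/(v + u) downstream (flow-assisted; a `free`
mode charges nothing, for sensitivity analysis). Water speed is the scalar
magnitude at the destination centroid for every direction — no directional
projection is attempted. An agent with no viable destination holds and
accrues no time: holding is not bursting. Exhaustion is checked after each
move, success first; a passed agent's recorded time can therefore exceed T
by at most one move. Burst speed is drawn once at creation and kept for
life.

**Vectorisation and randomness.** Agents never interact, so the engine
advances the whole cohort one timestep at a time with array operations. One
`numpy` Generator is seeded per run; every timestep consumes exactly one
uniform per active agent in agent-index order (spawn draws first, then IBM
burst speeds, then movement). Consequences: runs are bit-reproducible given
the seed, and a run's trajectory prefix is identical across different
`max_timesteps` budgets, which makes efficiency exactly non-decreasing in
the timestep budget rather than only statistically so.

## Ascent-time extrapolation and design charts

Flow statistics barely vary along the pass, so a passed agent's ascent time
scales linearly: L_max = L_sim · T / t_ascent. The pass length achievable at
target efficiency e% is the largest L such that ≥ e% of agents have
L_max ≥ L — the (1 − e/100) upper quantile of the L_max sample, computed as
the ⌈n·e/100⌉-th largest value. Failed and exhausted agents contribute
L_max = 0, so targets above the raw pass rate correctly return 0 rather than
an optimistic length. Observed-count efficiency is 100·s/a, and with
reallocation 100·s/(a + c/2) where c is the unassigned centre-attempt count
split evenly between the two stud families; fractional counts are accepted
because field studies report trial means.

## Synthetic flow-field generator

The generator emulates the *output* of a CFD solution for the small-stud
strip of the dual-density tile, not its physics (no RANS/VOF solving, no
unsteadiness or vortex shedding). Geometry: 50 mm tapered studs, small
14.8 → 11.7 mm diameter at 45.45 mm spacing, large 29.6 → 23.4 mm at
83.3 mm, staggered rows laid out symmetrically about the strip midline, one
grid-cell dry wall strip at each spanwise edge. The stud cross-section at
the 3 mm sampling plane interpolates the taper linearly.

Bulk scale: a Manning-type closure U = (1/n_cal) h^(2/3) √(sin θ) with
continuity U·h = f·q is solved for h by Brent root finding. Two constants
are calibrated once by inversion at the validated anchor (θ = 11°,
q = 3.33×10⁻³ m² s⁻¹, U = 0.299 m s⁻¹, h = 5.58 mm): n_cal ≈ 0.04596 and
the near-bed discharge fraction f ≈ 0.5010. The fraction is physically
necessary — the observed U·h at the 3 mm plane of the small-stud strip is
about half the nominal inflow unit discharge, because the tile splits flow
between the small- and large-stud strips (in the 45:83 spacing ratio, which
the generator applies when asked for the large family) and the sampling
plane sits inside the boundary layer. The closure interpolates smoothly in
(θ, q) and is strictly monotone — U increases with both θ and q — but away
from the anchor it is an emulation device, not a solver prediction.

Local structure: speed = U × shape(x, z), with a Gaussian stagnation deficit
(amplitude 0.60) ahead of each stud face, an exponential wake deficit
(amplitude 0.40, e-folding length one stud diameter) behind it, both
laterally Gaussian with the stud radius as scale; the inter-stud convergence
excess emerges from renormalising the wetted mean to U exactly. The
amplitudes are free calibration constants chosen so the streamwise-averaged
spanwise profile spans roughly 0.83–1.11 of the mean at the anchor —
bracketing the reported extremes (0.26 and 0.37 m s⁻¹ around a 0.299 mean).
Depth is anticorrelated with the relative speed excess (coefficient 0.7,
matching the reported sheltered maxima / inter-stud minima pattern) and
renormalised so the mean depth equals the closure's h. Optional
multiplicative log-normal noise is off by default; with it off the generator
is exactly deterministic and mirror-symmetric about the strip midline.

What passing tests on these fields show: that the models respond correctly
to the *structure* CFD fields exhibit (sheltered slow lanes, fast inter-stud
lanes, blocked versus connected topologies, monotone bulk response to θ and
q). What they cannot show: agreement with any particular solver's field —
the original study's CFD output is not deposited, so its headline
efficiencies (e.g. the 75.5% IBM / 97.8% CA comparison case) are not
reproducible here and are deliberately not asserted anywhere.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale configurations
chosen as sensible defaults for interactive work: 2.5 mm cells on a
0.30 m × 0.045 m strip (120 × 18 cells) with 300–400 agents for sweep
scenarios, and 0.5 mm cells on width-1 corridors (the closed-form oracle
case) with 2000 agents. Coarser cells than the reference 0.5 mm change the
exhaustion granularity slightly but not the linear time scaling. The
Manning closure is solved to |residual| < 10⁻¹⁴ relative; the uniform-field
closed form 100·(1 − F(u + L/T)) ignores the one-move discretisation of the
exhaustion boundary, which biases the comparison by well under one
percentage point at 0.5 mm cells.

Ties inside a priority group are broken by a single uniform draw mapped as
⌊u·k⌋, identically in the vectorised engine and the single-agent reference
implementations, so both select with the same distribution.

## Known limitations

* Time-averaged fields only: no vortex shedding, no station-holding against
  unsteady flow, no time-dependent passage windows.
* One agent = one 0.5 mm cell; real elvers cannot thread one-cell-wide gaps.
* The exhaustion budget counts swim time only; drag-related energetics,
  crawling/climbing, predation, motivation and pass-finding are out of scope.
* The synthetic generator's (θ, q) response away from its single calibration
  anchor is smooth and monotone but unvalidated.
* Season/temperature corrections to burst speeds are metadata only; the
  quantile table is the user's responsibility.
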