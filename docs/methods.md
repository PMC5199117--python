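# Methods

`lexiplan` implements wish-list driven, two-phase ε-constraint (2pεc)
lexicographic fluence optimization for concave pelvic targets, together with
the synthetic phantoms, plan-quality metrics and paired cohort statistics
needed to exercise the method end to end without clinical data. This note
documents the models, the defaults and why they were chosen, the numerical
machinery, and what the synthetic setting does and does not demonstrate.

## The planning problem

A treatment plan is a nonnegative fluence vector `x` (one weight per
beamlet). A dose-influence matrix `A ≥ 0` maps fluence to per-voxel dose
`d = A x` (Gy). Planning goals are expressed as a *wish-list*:

* **Hard constraints** — maximum-dose limits that every solve must respect
  voxelwise (here: PTV ≤ 105 % of the prescription `D^p`, the 40 mm PTV
  shell ≤ 50 %, unspecified tissue ≤ 105 %).
* **Prioritized objectives** — convex costs minimized one priority level at
  a time. The shipped default list (priorities 1–14) opens with target
  coverage (LTCP on the PTV, goal 0.5, α = 0.8 Gy⁻¹), then small-bowel
  sparing (EUD k=4 goal 45 Gy, EUD k=3 goal 15 Gy, mean 10 Gy, max `D^p`),
  conformity shells at 3/15/25 mm (95 %/75 %/60 % of `D^p`), a 2 cm skin
  ring (35 %), and EUD/mean objectives for sigmoid, colon, bladder and
  rectum. Equal priority numbers form groups (7, 9, 12).

### Cost functions

With `d_i` the member-voxel doses of a structure of `N` voxels:

* `LTCP(d) = (1/N) Σ exp(−α (d_i − D^p))` — a convex coverage surrogate,
  equal to 1 at uniform `D^p` and 0.5 when every voxel exceeds `D^p` by
  `ln 2 / α`. Internally the optimizer works with `log LTCP` (a log-sum-exp
  of affine functions — convex and numerically stable even at zero dose,
  where the raw value is ~e^{37}).
* `gEUD_k(d) = ((1/N) Σ d_i^k)^{1/k}` — the generalized mean. `k = 1` is
  the arithmetic mean and `k → ∞` the maximum; `k < 1` is rejected because
  that regime is not convex. All shipped OAR entries use `k ∈ {3, 4}`.
* mean and maximum dose — the linear special cases. Maximum-dose
  objectives are handled exactly with an auxiliary bound variable `t` and
  per-voxel rows `d_i ≤ t`; no smooth surrogate of the max is used.

### The 2pεc procedure

*Phase 1* walks the priority levels in ascending order. Each level is
solved as one convex program (groups: the unweighted sum of goal-normalized
members) subject to the hard constraints and all previously imposed
ε-constraints. The attained value then becomes an ε-constraint for every
later stage: **at the goal** when the goal was met (this deliberately leaves
slack for lower priorities), otherwise at `attained · (1 + δ)` with
δ = 0.03 by default; the slack prevents ill-conditioning from constraints
active exactly at the previous optimum.

Phase-1 stages are *goal-directed*: the solve may terminate as soon as the
goal value is reached at a point feasible for the full constraint set,
because the imposed bound is the goal either way and no later stage can be
affected. Stages whose goal is already met at entry cost nothing. When a
goal is unattainable (the shipped LTCP goal of 0.5 usually is, under the
105 % cap and the 50 % shell), the stage runs to its constrained minimum.

*Phase 2* revisits every objective in the same order, minimizes it fully
under all current constraints, and tightens its bound to
`min(previous bound, attained · (1 + δ))` — bounds never loosen, so the
final plan provably respects every bound in the trace. This phase is the
"or even superseded" behaviour: high-priority objectives are pushed below
their goals where the lower priorities left room.

A *coverage safeguard* enforces the clinical acceptability rule: after
normalizing a copy of the plan to median PTV dose `D^p`, the PTV V95 must
reach 99.5 %. If not, the LTCP ε-bound is halved and both phases re-run, up
to 3 retries. The returned plan itself is never normalized (normalization
is an evaluation-time convention).

## Synthetic phantoms

The generator emulates the pelvic geometry the wish-list was designed for,
on a regular voxel grid (default 5 mm isotropic, 48×48×21; all distances
are exact Euclidean distances between voxel centers, anisotropic voxels
supported):

* elliptical body outline (semi-axes 108 × 92 × 70 mm);
* an elongated cervix-uterus target: a column of radius 28 mm and
  half-height 24 mm. The target is extruded (constant cross-section over
  its z-extent) rather than spherical: with one 1-D beamlet row per beam,
  fluence cannot vary along z, and only a z-uniform silhouette can be
  conformally covered at every slice;
* a spherical bladder that carves into the target column from anterior.
  The `concavity` parameter (0–1, default 0.6) sets the carve depth; the
  PTV (ITV expanded isotropically by 10 mm) then wraps the bladder as a
  horseshoe. The PTV's convex-hull fill fraction decreases monotonically
  with `concavity` — the generator's knob for emulating empty- versus
  full-bladder target shapes;
* small bowel (a bag of loops superior-anterior), rectum (posterior tube),
  sigmoid (curved tube between them) and an optional colon — all jittered
  by the seed and clipped against body, PTV and each other;
* derived planning structures: shells at 3/15/25/40 mm from the PTV
  surface (thin rings, default thickness two voxel widths, clipped to the
  body), a 20 mm skin ring measured from the body contour inward, and
  unspecified tissue (body minus PTV and organs). Shells do not subtract
  organs — where a shell crosses the small bowel both costs see the voxel.

Identical `(seed, params)` produce bit-identical masks.

## Toy dose model

The dose engine is a deliberately simple pencil-beam model; every result in
this package is defined relative to it.

* Equi-angular coplanar beams (default 20; 9 also used), parallel rays, no
  divergence.
* One 1-D row of beamlets per beam (default width 5 mm) spanning the PTV
  projection plus a 10 mm margin.
* Entry `(i, j)` of the influence matrix:
  `dose_scale · exp(−μ · depth_ij) · exp(−lat_ij² / 2σ²) · g(z_i)`, with
  depth measured from the body entry along the ray, a lateral Gaussian
  penumbra of σ = 3 mm (cut off at 3σ for sparsity), and `g` a jaw profile
  in z: flat over the PTV z-extent + 5 mm, Gaussian roll-off with σ = 8 mm
  outside. The jaw is what controls superior-inferior fall-off, since the
  fluence itself is z-uniform.
* μ defaults to 0.035 cm⁻¹ — an *effective broad-beam* attenuation for a
  10 MV beam. The model has no scatter buildup, so the narrow-beam
  coefficient (≈0.045–0.05 cm⁻¹) would overstate depth-dose fall-off and,
  in this geometry, make the 50 % shell constraint incompatible with
  prescription-level target dose.
* No heterogeneity, no scatter kernels, no MU or delivery-time modeling.

## Stage solver

Each stage is a convex program: minimize a smooth convex objective (or an
epigraph variable for max-type objectives) over `x ≥ 0` subject to many
linear per-voxel rows (hard caps, max-type ε-bounds, epigraph rows) and a
few smooth convex scalar ε-constraints (LTCP in log space, gEUD, mean).

The solver is an augmented-Lagrangian (PHR) outer loop:

* **Inner solves** — bound-constrained L-BFGS-B by default; a projected
  Newton variant (exact Hessians of the augmented Lagrangian, Cholesky on
  the free set, Gram matrix of near-active cap rows frozen between
  refreshes) is available via `OptimizerSettings(inner_solver="newton")`
  and is used by the test suite on miniature instances, where it finishes
  with an exhaustive active-set (KKT) polish: every subset of candidate
  constraints is solved as an equality system and the best feasible point
  wins — complete at that dimension.
* **Lazy rows** — per-voxel cap rows enter the Lagrangian through a
  working set (hottest voxels plus any row found violated when the full
  sets are scanned after each outer iteration); multipliers persist across
  stages and rows far below their limit are pruned between stages.
* **Multiplier safeguards** — dual estimates are zeroed for constraints
  that are clearly inactive (complementary slackness), and the scalar
  ε-constraints carry a separately escalating penalty because their duals
  otherwise converge slowly relative to the cap hinges.
* **Warm starts** — each stage starts from the previous stage's solution;
  the very first from a linear-programming warm start (HiGHS): maximize the
  minimum PTV dose under sampled caps, with a mild mean-dose tie-break.

Tolerances: the solver targets a relative feasibility of 1e−5 and accepts a
stage result when the worst relative constraint violation is below 1 % of
the limit (`feas_accept`, default 1e−2) — at most ~0.5 Gy on a 48 Gy cap,
below the fidelity of the toy dose model itself; in practice cohort plans
land within ~0.1 % of the caps, and the acceptance script reports raw
maxima so the tolerance is visible, not hidden. The
outer loop stops when the full constraint set is satisfied and the
objective is stable to `ftol` (default 3e−4 relative); the ε-bounds carry
3 % slack, so sub-0.1 % objective precision has no downstream effect. The
optimizer contains no randomness; identical inputs give identical plans.

Problem sizes were chosen so a full 10-phantom cohort plans in a few
minutes on one core: the 5 mm default grid leaves ≈1 700 PTV voxels and
≈380 beamlets for 20 beams. The grid is a documented accuracy parameter of
the volume metrics (voxel counting, no partial-volume interpolation).

## Plan evaluation and comparison conventions

* OAR V_x metrics use strict `>` ("receiving more than x Gy"); target
  coverage V95/V110 and the conformity index CI95 use inclusive `≥`
  ("receive ≥ 95 %"). CI95 counts *all* grid voxels at ≥ 95 % of `D^p`
  over the PTV voxel count.
* The clinical acceptability rule (V95 ≥ 99.5 %, V110 ≤ 0.2 %) is
  inclusive at both boundaries.
* Median normalization rescales fluence so the median PTV dose equals the
  target exactly (linearity makes every other dose scale by the same
  factor).
* The paired Wilcoxon signed-rank test removes zero differences, uses
  mid-ranks for ties, and is exact for n ≤ 25: the null distribution of
  the positive-rank sum is built by convolution over all 2ⁿ sign
  assignments and the two-sided p-value is the probability of a deviation
  from the null mean at least as large as observed (the null is symmetric
  even under ties). Larger n uses the normal approximation with tie
  correction and no continuity correction. All differences zero gives
  p = 1.0 by convention. No multiple-testing correction is applied.
* `compare_pair(a, b)` reports `Δmean = mean(a − b)` with sample SD, the
  percentage difference `100 · Δmean / mean(a)`, and win counts
  `(count b < a | count a < b)` — the first element counts plans where the
  second cohort is strictly lower, matching the convention that a positive
  Δmean favours the second strategy; ties are counted separately, never
  split. The rendered matrix places Δmean ± SD below the diagonal and
  p-values with win counts above it.

## What the synthetic setting shows — and what it does not

Passing plans demonstrate that the lexicographic machinery does what it
claims *under the documented toy model*: hard caps hold voxelwise, the
priority order is protected by the ε-bounds, coverage criteria are met on
every cohort member, and the comparison statistics are exact. The phantoms
emulate the geometric essentials (a concave target wrapping an unconstrained
organ, small bowel abutting the target superiorly, near-target shells) but
not CT heterogeneity, scatter, deliverability (MLC sequencing, arcs), organ
deformation, or inter-patient anatomical variability; absolute OAR numbers
(e.g. small-bowel V45 around 14–22 % across seeds) are therefore properties
of the phantom family and dose model, not clinical predictions — although
they land in the range reported for real automated plans of this site.

## Known limitations

* Fluence is z-uniform (slab geometry); superior-inferior conformality
  comes entirely from the fixed jaw profile.
* The stage solver's documented feasibility tolerance (1 % of a limit)
  is coarser than interior-point planning systems achieve; maxima reported
  by the acceptance script can exceed a cap by up to that fraction
  (observed cohort maxima stay within ~0.1 %).
* Phase-2 "full" minimization is bounded by the outer/inner iteration
  budgets; bounds and feasibility are always honoured, but an objective may
  stop short of its exact constrained minimum by more than `ftol` on badly
  conditioned stages (the ε-slack δ absorbs this downstream).
* The colon is generated only on request; the default wish-list rows for
  colon are skipped with a warning when it is absent.
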