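# lexiplan

Wish-list driven, lexicographic multi-criteria fluence optimization for
concave pelvic radiotherapy targets — with synthetic phantoms, plan-quality
evaluation and paired cohort comparison, so the whole pipeline runs end to
end without clinical data.

## Who this is for

Researchers in automated treatment planning who want a transparent,
self-contained reference implementation of prioritized (lexicographic)
plan optimization: medical physicists prototyping wish-lists, students
studying multi-criteria optimization in radiotherapy, and developers who
need a reproducible sandbox in place of a proprietary treatment planning
system.

## The method

Planning goals are a *wish-list*: hard maximum-dose constraints that every
solve must satisfy, plus objectives with priorities. For fluence `x ≥ 0`
and dose `d = Ax`, the two-phase ε-constraint (2pεc) procedure is

1. **Phase 1** — for each priority level in order, minimize the objective
   subject to the hard constraints and all ε-constraints imposed so far;
   then impose its value as an ε-constraint: at the *goal* g when attained
   (`f ≤ g`), else at `f* (1 + δ)` with δ = 0.03.
2. **Phase 2** — revisit each objective in the same order, minimize it
   fully under all current constraints, and tighten its bound to
   `min(previous, f* (1 + δ))`.

The result is a Pareto-optimal plan in which no lower-priority objective
was improved at the expense of a higher one. The shipped default wish-list
is the clinically tuned cervix list: coverage first via the logarithmic
tumor-control surrogate `LTCP = (1/N) Σ exp(−α (d_i − D^p))` (goal 0.5,
α = 0.8), then small-bowel sparing through generalized-EUD
(`gEUD_k = ((1/N) Σ d_i^k)^{1/k}`), mean and maximum objectives, dose
fall-off shells around the PTV and a skin ring, with hard caps at 105 % of
the 46 Gy prescription on PTV and unspecified tissue and 50 % on the 40 mm
shell. A coverage safeguard guarantees the clinical acceptability rule
(PTV V95 ≥ 99.5 %, V110 ≤ 0.2 % after normalization to median PTV dose).

Synthetic pelvic phantoms (elliptical body, horseshoe PTV wrapping the
bladder with a tunable concavity, small bowel, rectum, sigmoid, derived
shells and skin ring) and a documented toy pencil-beam dose model supply
the input; DVH metrics, the conformity index CI95 and exact paired
Wilcoxon signed-rank statistics evaluate and compare the plans. See
`docs/methods.md` for the full model description and numerical choices.

## Worked example

```python
import lexiplan as lp

phantom = lp.generate_phantom(seed=1)              # 48x48x21 grid, 5 mm voxels
planner = lp.FluencePlanner(phantom)               # Table-style wish-list, 20 beams
result  = planner.fit()                            # 2-phase epsilon-constraint solve
print(result.summary())
```

Output (abridged — exact numbers for seed 1 at the defaults):

```
Lexicographic fluence plan
============================================================
beams: 20 equi-angular, 380 beamlets, D^p = 46 Gy
PTV: V95 = 100.00%  V110 = 0.000%  median = 46.59 Gy  max = 48.12 Gy
CI95 = 1.526   clinical acceptance: PASS
------------------------------------------------------------
structure         Dmean (Gy)   Dmax (Gy)   V45 (%)   V15 (%)
small_bowel            33.74       48.33     21.93     96.68
bladder                45.60       46.75
rectum                 32.57       48.31
sigmoid                41.85       48.32
------------------------------------------------------------
stage                          phase    attained       bound
p1:ptv:ltcp                        1      0.5927      0.6105
p2:shell_3mm:max                   1       48.31       49.75
p4:small_bowel:eud                 1       37.65          45
...
```

Reading this: every PTV voxel sits between 95 % and 110 % of the
prescription after median normalization (the clinical acceptance rule),
the hot spot stays under the 105 % hard cap, and the trace shows each
objective's attained value with the ε-bound it imposed on later stages —
the bladder, sitting inside the target's concavity, ends near target dose
while the rectum and small bowel are pulled down as far as the higher
priorities allow. `result.normalized()` rescales to an exact median PTV
dose, `result.plot_dvh()` draws the cumulative DVHs, and
`lexiplan.comparison_table(...)` builds the pairwise cohort comparison
(Δmean ± SD, percentage differences, win counts, exact Wilcoxon p-values).

A thin CLI wraps the same library calls:

```sh
lexiplan phantom --seed 1 --concavity 0.6 --out ph/
lexiplan optimize --phantom-dir ph/ --beams 20 --out plan/
lexiplan evaluate --dose plan/dose.nii.gz --phantom-dir ph/
```

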