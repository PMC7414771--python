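# Methods

This note documents the models, conventions and numerical choices behind
`scnet`, in the order the pipeline runs them.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: 49
subjects split 16 Val homozygotes / 33 Met carriers (BDNF Val66Met genotype
counts 16/28/5), 68 Desikan–Killiany regions, ages drawn from a normal
(41.1 ± 11.3 yr) truncated to [20, 65] by rejection, male fraction 36/49.
Groups follow the Met-allele rule (carrier of ≥1 Met allele ⇒ Met group).

Genotypes are assigned by largest-remainder apportionment of
`genotype_probs × n` (so the default cohort reproduces the 16/28/5 counts
exactly at every seed) with a `genotype_sampling="multinomial"` option for
genuinely random counts.

Thickness for subject s in region r is

```
t_sr = baseline + β_age·age_s + β_gender·male_s + β_int·age_s·male_s + σ·z_sr
```

with `baseline = 2.8 mm`, `β_age = −0.008 mm/yr` (mild cortical thinning),
`β_gender = −0.03 mm`, `β_int = 0`, `σ = 0.12 mm` — values in the range
reported for adult cortical thickness; the residual vectors `z_s` are
multivariate normal with a group-specific correlation matrix. That matrix
has `r_within` inside bilateral lobar modules, `r_between` across modules,
and `r_homotopic` on left–right counterpart pairs (region i pairs with
i + N/2 under the default label order), repaired to positive definite by
eigenvalue clipping (floor 1e-8) with diagonal renormalisation, iterated to
convergence. The thickness noise model is the module's own assumption — the
study the pipeline reproduces does not state one.

Group defaults are `r_within = 0.40` (Val) vs `0.60` (Met),
`r_between = 0.15`, `r_homotopic = 0.70/0.75`. The Met elevation was
calibrated once against the target segregation effect — an average
local-efficiency gap of ≈ 0.14 between the two group networks at the study
geometry — and then frozen; under the fixed-0.5-cutoff pipeline the
calibrated alternative uses `r_within(Met) = 0.65`, which yields a mean
realized gap of 0.15 ± 0.05 across seeds. Because generated data are
multivariate normal, empirical Spearman correlations converge to
(6/π)·asin(r/2) ≈ r − 0.02 of the Pearson targets; tests therefore check
class-averaged correlations within ±0.05.

What the generator does **not** emulate: spatially varying regional
baselines, measurement artefacts, non-Gaussian thickness distributions,
site effects, education-years effects, and any genuine biological coupling
between covariates and correlation structure. Passing tests show the
pipeline's statistics behave correctly under its own assumptions, not that
the biological effect exists.

## Cohort statistics

- HWE: uncorrected Pearson χ² of observed genotype counts against n·p²,
  2npq, n·q² with allele frequencies estimated from the sample. The
  conventional test has df = 1; the df = 2 p-value is also reported because
  published tables are sometimes computed that way (the study's own printed
  p of 0.363 corresponds to df = 2 while it prints df = 1 — both numbers
  are exposed rather than guessing intent). Monomorphic samples return a
  flagged zero statistic.
- Fisher exact (gender): two-sided by the probability-mass rule (sum of all
  same-margin tables with probability ≤ observed); no mid-p.
- Age/education: Wilcoxon–Mann–Whitney, exact when both n ≤ 10 without
  ties, tie-corrected normal approximation otherwise.
- Per-region group t-tests: two-sided two-sample t per region on
  residualized thickness; Bonferroni by default (`fdr_bh` optional — the
  study names no method, and Bonferroni is the conservative choice);
  zero-variance regions are flagged undefined and excluded from the
  correction count.

## Residualization

All five candidate models include an intercept; gender enters as a 0/1
indicator (male = 1). AIC uses the Gaussian profile form
`n·ln(RSS/n) + 2k` with k = coefficients + 1 (variance); any
constant-offset AIC variant ranks models identically. Ties break toward
fewer parameters (candidates are scanned in ascending complexity and must
strictly improve). Rank-deficient designs (e.g. single-gender cohorts) drop
inestimable trailing terms with a warning. Residualization happens once, on
the pooled cohort, before any permutation; this matches a pipeline in which
the permutation shuffles rows of already-corrected data. (Re-fitting inside
each permutation is not offered: with group-blind covariate models the
residuals are permutation-invariant anyway.)

## Network construction

Spearman ρ uses average ranks for ties; a constant region has undefined
correlations, which become zero weights under a logged warning so the node
set stays fixed. Weights are |ρ| (`absolute`, the default) or positive-part
ρ (`positive_only`, the negative-edge-removed sensitivity variant).
Thresholding is closed (w ≥ t retained) — at grid step 0.01 the open/closed
distinction is immaterial but must be fixed for reproducibility.

### RMT threshold scan

For each grid value t ∈ {0.00, 0.01, …, 0.95} the weight matrix entries
below t are zeroed (unit diagonal restored) and the eigenvalue
nearest-neighbour spacing distribution (NNSD) is computed: eigenvalues are
deduplicated (1e-8 rounding; thresholded matrices are massively
degenerate), unfolded by a monotone PCHIP spline through 20 quantile knots
of the empirical cumulative spectral density, and the spacings (normalised
to unit mean) are binned at width 0.4 up to 3 with an open tail, merging
bins until each expects ≥ 3 counts. Two χ² distances are computed: to the
Poisson law e^(−s) and to the GOE Wigner surmise (πs/2)e^(−πs²/4).

A grid point qualifies as *Poisson-like* when the Poisson χ² is smaller
than the GOE χ² **and** its goodness-of-fit p ≥ 0.05. Grid points where
fewer than 10 distinct eigenvalues survive, or where fewer than half the
nodes retain any edge, are ineligible (the graph has been destroyed, not
thresholded). The chosen threshold is the first grid point opening a run of
3 consecutive eligible Poisson-like points. Requiring sustainment over a
short run rather than to the end of the grid is deliberate: partially
depleted modules at high cutoffs transiently regain level repulsion
(GOE-like spacings) before the network fragments, so a global-sustainment
rule is frequently undecidable. The knot count and bin width were fixed
against two structural oracles — a pure-noise Spearman matrix must look GOE
at t = 0, and a two-block matrix with a gap between background and block
correlations must transition inside the gap — before any downstream
results were measured. When no transition is found the scan returns `None`
with a diagnostic and callers fall back to a configurable fixed cutoff
(0.3 by default); the full scan table is exported for audit, since the
original study does not print its selected thresholds.

## Global measures

- Path lengths are 1/w; distances come from a vectorised Floyd–Warshall
  (n ≤ 64) or scipy Dijkstra. avgSPL averages over unordered *reachable*
  pairs only, logging the unreachable count.
- C_i (Barrat) and E_loc(i) use ordered neighbour pairs with the printed
  normalisations s_i(k_i − 1) and k_i(k_i − 1), which make a closed
  triangle's C exactly 1; nodes with k ≤ 1 contribute 0 and the averages
  divide by N.
- E_loc's d_jh is measured in the **full network** by default — the literal
  reading of the formula (which also lets paths run through i itself); a
  `neighborhood_subgraph` convention switch restricts paths to nn(i) for
  users wanting the Latora–Marchiori convention.
- SW nulls permute edge weights over the existing topology (degree
  sequence preserved, strengths not); rewiring nulls are out of scope. The
  null means use an exact-constant shortcut so all-equal-weight networks
  give SW = 1 with no rounding drift.
- Q is evaluated over ordered pairs including i = j (w_ii = 0). The
  single-module partition has Q = 0 identically; the annealer's result is
  floored at the better of the single-module and all-singletons baselines.

### Simulated annealing

Moves: single-node reassignment (85 %), module merge (7.5 %), random
bipartition split (7.5 %); Metropolis acceptance with geometric cooling
(defaults T₀ = 1, ratio 0.995, floor 1e-5, N² proposals per stage, best of
5 restarts). ΔQ for single-node moves is O(1) via maintained node-to-module
weight sums; the kernel is numba-compiled and seeded, so results are
bit-reproducible. The reported Q is recomputed from the returned partition,
guarding against incremental drift. `FAST_SA` (T₀ = 0.02, ratio 0.9, N²/2
moves, 1 restart) is the schedule used inside permutation loops, where the
same optimizer is applied symmetrically to observed and null networks; on
graphs of ≤ 8 nodes both schedules recover the exhaustive-search optimum.

## Permutation comparison

Pseudo-groups are uniform random partitions into the original sizes; all
five measure differences are computed from the same permutation set. Both
one-sided p-values are plain indicator means with *strict* inequalities —
ties count in neither tail, so p_greater + p_less = 1 − ties/tpc, and a
p-value of exactly 0 is possible (the study's formula has no add-one
smoothing; a `smoothed` flag provides (b+1)/(tpc+1) for users who want a
positive floor). Significance is flagged one-sided in the direction of the
observed difference at α = 0.05/5 = 0.01; pre-registered directions can be
supplied instead. The threshold policy defaults to re-running the RMT scan
inside every permutation (full-pipeline null); `fixed` reuses one cutoff
for speed. Sub-seeds for each permutation's small-world nulls and annealing
restarts spawn deterministically from the master seed, so the whole test is
reproducible bit for bit. A permutation whose thresholded network is empty
is redrawn with a logged count (the original study does not say how it
handled these; redraw keeps the null conditional on analysable networks).

## Problem sizes in tests and the acceptance script

The statistical-calibration tests use reduced designs chosen for
Monte-Carlo affordability: the type-I check runs 200 replicates of
12-region, 12+12-subject null cohorts at tpc = 200 with a fixed 0.3 cutoff
(under the null, exchangeability makes the calibration exact for any fixed
configuration), and the power check runs the full 68-region study geometry
with the calibrated alternative at tpc = 200, computing only the measures
it tests. The acceptance script runs the complete pipeline at the study
geometry with tpc = 200, n_null = 50 and the `FAST_SA` schedule.

## Known limitations

- The RMT decision rule is a design choice among several in the
  literature; on 16-subject groups the scan frequently finds no transition
  (rank-deficient Spearman matrices), and results can be sensitive to the
  fallback cutoff — the scan log is the audit trail.
- SW is undefined for networks without triangles (zero null clustering);
  the pipeline raises rather than imputing.
- The permutation test's p-values are conditional on the configured
  pipeline; comparing p-values across different threshold policies is not
  meaningful.
- Education years are carried as a covariate column but not modelled by
  the generator.
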