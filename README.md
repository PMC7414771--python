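# scnet — structural correlation networks from regional cortical thickness

`scnet` implements a group-level structural correlation network (SCN)
analysis for cortical thickness, of the kind used to ask whether a genotype
(here BDNF Val66Met: Val homozygotes vs Met carriers) changes the
integration, segregation or modular architecture of the brain's
morphometric covariance. It is aimed at neuroimaging researchers who have a
subjects × regions thickness table (e.g. FreeSurfer Desikan–Killiany
output) plus per-subject covariates, and at methodologists who want a
tested, reproducible reference for the weighted-network statistics
involved.

## The analysis

1. **Cohort statistics** — Hardy–Weinberg equilibrium χ² on genotype
   counts, Fisher's exact test on gender, Wilcoxon–Mann–Whitney on age, and
   per-region two-sample t-tests with multiple-testing correction.
2. **Residualization** — per region, the minimum-AIC linear model from
   {1, age, gender, age+gender, age×gender} is fitted on the pooled cohort
   and its residuals replace raw thickness.
3. **Network construction** — per group, Spearman correlations ρ across
   subjects for all region pairs; edge weights w_ij = |ρ_ij| (optionally
   dropping negative edges); a random-matrix-theory (RMT) threshold scan
   picks the cutoff where the surviving matrix's eigenvalue
   nearest-neighbour spacing distribution transitions from Wigner–Dyson
   (GOE, noise) to Poisson (signal) statistics.
4. **Global measures** — with strengths s_i = Σ_j w_ij, degrees
   k_i = Σ_j sign(w_ij), and path lengths 1/w_ij:
   - avgSPL: mean shortest-path distance over reachable pairs;
   - avgLCC: mean Barrat weighted clustering
     C_i = [Σ_{j,h∈nn(i)} (w_ij + w_ih)/2 · sign(w_ij w_ih w_jh)] / [s_i (k_i − 1)];
   - avgLEFF: mean local efficiency
     E_i = [Σ_{j≠h∈nn(i)} 1/d_jh] / [k_i (k_i − 1)];
   - SW: (avgLCC/avgLCC_rand)/(avgSPL/avgSPL_rand) against 100
     weight-permuted null networks;
   - Q: weighted modularity
     Q = (1/2W) Σ_ij (w_ij − s_i s_j / 2W) δ(c_i, c_j),
     maximized over partitions by simulated annealing.
5. **Permutation comparison** — subjects are re-partitioned into
   pseudo-groups of the original sizes (tpc = 1000 by default), both
   networks are rebuilt per permutation, and one-sided p-values are plain
   indicator means of the null measure differences, Bonferroni-controlled
   at 0.05/5 = 0.01.

A synthetic-cohort generator (module-structured, homotopically symmetric
inter-regional correlations with additive age/gender effects) stands in for
MRI data, so the entire pipeline is testable end to end.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 7
python analysis/02_cohort_stats.py
python analysis/03_residualize.py
python analysis/04_build_networks.py
python analysis/06_permutation_test.py --seed 7 --tpc 200
```

prints (abridged):

```
wrote results/cohort.csv: 49 subjects x 68 regions
genotypes: {'Val/Met': 28, 'Val/Val': 16, 'Met/Met': 5}
HWE chi2 = 2.03 (p = 0.154 at df=1, 0.363 at df=2)
Val/Val fraction = 32.7%
  intercept+age: selected for 50 regions
ValHomozygote: n=16 subjects, threshold=0.30 (fallback), 947 edges, total weight W=433.7
MetCarrier: n=33 subjects, threshold=0.30 (fallback), 766 edges, total weight W=387.0
         observed_diff  p_greater  p_less  p_directional  significant
avgLEFF       0.100713      0.020   0.980          0.020        False

Bonferroni per-test alpha = 0.01
```

Reading the output: the generated cohort reproduces the target genotype
composition (16/28/5, hence 32.7 % Val/Val and HWE χ² = 2.03); age is the
dominant covariate in most regions; at this seed the RMT scan found no
Poisson transition for either group network, so both fall back to the 0.30
cutoff; the Met-carrier network's average local efficiency exceeds the Val
network's by 0.10, with a one-sided permutation p of 0.020 at tpc = 200 —
suggestive but above the Bonferroni threshold 0.01 for this realization.

The same pipeline runs on real data via
`scnet all --config pipeline.yaml --out results/run` or
`scnet stats your_cohort.csv` (any delimited subjects × regions table with
`group`, `genotype`, `age`, `gender` columns).

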