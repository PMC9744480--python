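# Methods

## Model and statistics

For a cohort of `n` individuals with centered quantitative phenotype `y`
(`Σᵢ y(i) = 0`) and a set of `l` biallelic sites, each site `k` is stored
as the indicator decomposition `aₖ` (homozygous reference), `bₖ`
(heterozygous), `cₖ` (homozygous alternative), with `aₖ + bₖ + cₖ = 1`
elementwise and genotype value `gₖ = bₖ + 2cₖ` (the alternative-allele
count).  The alternative allele frequency is `p = (1ᵀbₖ + 2·1ᵀcₖ)/(2n)`
and the mean genotype value `μₖ = 2p`.

The per-site GRM matrix is `Xₖ(i,j) = (gₖ(i) − μₖ)(gₖ(j) − μₖ)`; its rows
sum to zero by construction.  Expanding around the uncentered outer
product `Gₖ = gₖgₖᵀ` gives
`Xₖ = Gₖ − μₖ1gₖᵀ − μₖgₖ1ᵀ + μₖ²11ᵀ`, and since `yᵀ1 = 0` all μ terms
vanish inside the quadratic form: `yᵀXₖy = yᵀGₖy = (yᵀgₖ)²`.  Hence

    Qₖ = (yᵀbₖ + 2·yᵀcₖ)².

The per-site IBS matrix counts shared alleles,
`IBSₖ = 2aₖaₖᵀ + 1bₖᵀ + bₖ1ᵀ + 2cₖcₖᵀ`; the two rank-one `1bᵀ` terms are
annihilated by centering and

    Rₖ = 2(yᵀaₖ)² + 2(yᵀcₖ)²,   with  yᵀaₖ = −yᵀbₖ − yᵀcₖ.

Both are exact identities, verified in the test suite against a
brute-force oracle that builds the explicit matrices with naive O(n²)
double loops and shares no code with the fast path.  The set statistic is
`S = Σₖ wₖQₖ` or `Σₖ wₖRₖ`; per-site terms are accumulated with exact
(`math.fsum`) summation so `S` is independent of site order.

When a site has no homozygous-alternative carriers, `yᵀcₖ = 0` and
`yᵀaₖ = −yᵀbₖ`, so `Rₖ = 2Qₖ` exactly — the two kernels differ only
through hom-alt carriers, which is why their power is expected to be
similar on rare-variant panels.

## Weights

Uniform weights (all 1) are the default, matching an unweighted sum over
sites.  A Beta-density weight evaluated at each site's minor allele
frequency is available (`WeightScheme.beta`), with the conventional
rare-variant shapes (1, 25) as its default parameters — offered, never
applied silently.  Explicit per-site weights are passed through after
validation (finite, nonnegative, one per site); weight files that fail to
cover every site are an error, because silently dropping a weight corrupts
`S`.

## Permutation test

The null distribution of `S` is approximated by resampling the phenotype
without replacement: `B` uniform random permutations of `y`, each
re-scored through the O(n) path (the genotype vectors are never permuted —
relabelling `y` is equivalent and cheaper).  The p-value is the add-one
estimator `(count_ge + 1)/(B + 1)` with ties counted as exceedances; it is
a valid permutation p-value, can never be exactly zero, and its smallest
attainable value is `1/(B+1)`.  Rejection uses `p ≤ α`; α is accepted in
`(0, 1]`, the degenerate boundary `α = 1` existing only so calibration
experiments can force rejection.  Permutations are drawn from a seeded
`numpy` Generator in fixed-size batches; the chunk iterator is public so
an independent evaluation (e.g. the matrix oracle) can replay the exact
permutation stream of a seeded run, which the tests do.

Per permutation the statistic costs O(n·l); no incremental-update tricks
are used.  Asymptotic p-values from chi-square mixtures are deliberately
out of scope: the permutation route makes no small-sample distributional
assumption.

## Synthetic cohorts

`simulate_genotypes` draws each site independently under Hardy–Weinberg
equilibrium at its alternative frequency `p` (hom-alt with probability
`p²`, het with `2p(1−p)`).  Monomorphic realizations — frequent at rare
`p` in finite cohorts — are excluded: dropped by default, or redrawn under
the `redraw` policy (capped at 10⁴ attempts).  The default panel is 7 rare
sites with alternative-allele counts 1, 2, 3, 4, 5, 8 and 10 out of 5008
haplotypes (n = 2504), chosen once to mimic the frequency spectrum of rare
functional variants in a single gene for a cohort of that size.

`simulate_phenotype` implements a carrier model: individuals carrying at
least one alternative allele at at least one causal site are shifted by
`carrier_effect` (default −1.0 trait units, e.g. µg/dL for a serum
metabolite), and independent Normal(0, `noise_sd`) noise (default SD 1.0)
is added to everyone.  An additive mode (one shift per causal site
carried) sits behind `effect_mode="additive"` for the reading of the
carrier definition in which sites act independently.  Genotype and
phenotype seeds are separate so a fixed panel can be retested under fresh
environmental noise, which is what `power_experiment` does by default
(`redraw_genotypes=True` resamples the panel per replicate instead).

What the simulator does **not** emulate: linkage disequilibrium between
sites (real gene panels are correlated; all sites here are independent),
population structure, covariates, and case-control ascertainment.  Tests
passing on these cohorts therefore demonstrate the correctness and
calibration of the statistics, not robustness to confounding.

## Numerical choices

* All statistics in double precision; per-site scalars via `np.dot`,
  aggregation via `fsum`.
* Oracle-vs-fast equivalence is asserted at 1e-9 relative tolerance; the
  rare-variant identity `R = 2Q` at 1e-12 (it is algebraically exact).
* Phenotype centering is two-pass (subtract the mean, then the residual
  mean) and validated at construction with tolerance `1e-12 ·
  max(1, max|y|)`; statistics never see uncentered values.
* Monomorphic sites contribute exactly 0 to both kernels (for the GRM
  `g − μ` is the zero vector; for the IBS, centering kills `(yᵀa)²`), so
  no special-casing is needed in the statistics; the file pipeline still
  excludes them since they carry no signal.
* Missing genotypes are an error by default, naming site and individual;
  `drop-site` and `ref-impute` policies are explicit opt-ins.  Half-calls
  (`./1`) are treated as missing — their allele count is undefined.
  Multiallelic records are skipped (file mode) or rejected (call mode).
* Tie convention: permuted statistics equal to the observed `S` count as
  exceedances.  The observed `S` (exact summation) and the vectorised
  permutation statistics agree to the last ulp or so; genuine float ties
  arise only from genuinely tied permutations (e.g. a constant phenotype),
  where both paths produce identical values.

## Problem sizes in the shipped experiments

The test suite's calibration experiment uses n = 500, 5 sites, B = 999 and
500 replicates (rejection rate checked against the exact binomial 99%
interval at α = 0.05); the power experiment uses the default n = 2504
rare-site panel with B = 999, α = 0.01 and 100 replicates per kernel.
Both scales were fixed as desk-scale profiles when the experiments were
designed; the CLI exposes `--paper-scale` (B = 10⁶, α = 5×10⁻⁶) for
full-scale runs.  The CLI's oracle commands are capped at n ≤ 5000 to
guard against accidental O(n²) blowups; the library imposes no cap.

## Known limitations

Binary phenotypes, covariate adjustment, dosage genotypes, sex-chromosome
ploidy, and eigenvalue-based analytic p-values are out of scope.  The
permutation engine has no adaptive early stopping; genome-scale α (e.g.
5×10⁻⁶) genuinely requires B on the order of 10⁶ permutations per test.
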