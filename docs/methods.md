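# Methods

## Relative expression and the normal reference

All statistics operate on percent-of-pool relative expression: within
each sample, the summed abundance of the RP gene set is set to 100% and
each gene's value is its share. The transformation is applied **per
sample first**, and group quantities (profiles, the normal reference)
are means of per-sample shares, not shares of pooled counts. This makes
the matched-sample, unmatched-sample and grouped analyses consistent:
they all see the same per-sample quantity. The input unit (counts, RSEM,
FPKM) is deliberately opaque — any nonnegative abundance works, because
the normalization removes per-sample scale exactly (`relative_percent`
is invariant under per-sample rescaling, and the suite property-tests
this).

The normal reference stores the per-gene mean μ_n and sample standard
deviation σ_n (denominator n−1) of relative expression across ≥ 2 normal
samples. The n−1 convention treats the normals as a sample from a
population of normal tissues; with the cohort sizes involved (tens of
normals) the choice is numerically minor but is fixed here for
reproducibility.

## The deregulation statistic set

* Per-transcript P-value: `P = 2·(1 − Φ(|x_t − μ_n| / σ_n))`, evaluated
  as `2·Φ(−z)` so that deep tails retain full double precision (the
  naive `1 − Φ(z)` underflows beyond z ≈ 8). The model assumption is
  that a transcript's relative expression across normal tissues is
  approximately normal; the synthetic calibration checks enforce
  exactly this regime. σ_n = 0 is a degenerate reference (possible only
  in toy data): P is defined as 1 when x_t = μ_n and 0 otherwise, and
  the position is flagged.
* Significant-transcript count: strictly `P < α` (a P exactly equal to α
  does not count).
* Cohort binomial test: under the global null each transcript trips the
  α threshold independently with probability α, so the per-tumor count
  is Binomial(n_genes, α). The cohort's mean count is **floored** and
  the one-sided upper tail `Σ_{j≥k} C(n,j) α^j (1−α)^{n−j}` is reported.
  The tail is summed in log space (`gammaln` + `logsumexp`), so values
  far below the double-underflow limit are exact; the suite checks
  agreement with an independent PMF-summation oracle at every k to
  < 1e−10 relative error. The flooring and the one-sided orientation
  are fixed because they jointly reproduce all four published cohort
  P-values (2.6e−17, 2.8e−15, 2.1e−12, 2.6e−5) from the published
  average counts (28.3, 26.2, 23.6, 14.6); rounding or ceiling does not.
* Total deregulation score: `Σ_g |x_t[g] − μ_n[g]|` in percentage
  points — absolute differences **of** relative expression, not percent
  differences relative to the mean (those are used only for the
  deviation area maps). The score is bounded by 200 for any pair of
  100-sum compositions.
* Quartiles: tumors ranked by score descending; the top and bottom
  ⌈N/4⌉ form the "upper" and "lower" strata. Boundary ties break by
  ascending sample ID so the assignment is deterministic.

`DeregulationModel.fit()` packages these per-cohort;
`DeregulationResults` carries the per-gene deviation and P-value
matrices, per-tumor counts and scores, the cohort test and the quartile
labels, with `summary()` for a console view.

## Grouped differential and variance statistics

Mouse-style group comparisons use two-sided Welch (unequal-variance)
t-tests per gene on relative expression, with Welch–Satterthwaite
degrees of freedom (delegated to `scipy.stats.ttest_ind`), and
Benjamini–Hochberg step-up q-values (`statsmodels.multipletests`);
significance means q < FDR (default 5%). Note the Welch test is mildly
conservative at very small group sizes (empirical size ≈ 4.4% at n = 5
per group, ≈ 4.9% at n = 10); the calibration checks use n = 10 where
the approximation is accurate. Direction is the sign of
mean(B) − mean(A); genes constant and equal in both groups are null
(t = 0, p = 1). The directionality overlap classifier partitions genes
into both-same-direction / both-opposite / only-A / only-B / neither —
the Venn-diagram summary of two comparisons.

Matched tumor-vs-normal variance comparisons use the F statistic
`s²_tumor / s²_normal` with (n_t−1, n_n−1) df. Sidedness is not
canonical for this design; the default is two-sided
(`2·min(lower, upper)` capped at 1), which is conservative for
"variance is greater in tumors" conclusions, and a one-sided flag
exposes the upper tail. Genes with zero variance on both sides are
reported untestable (flagged, excluded from the BH family) rather than
assigned p = 1.

## Survival

Kaplan–Meier curves use the standard product-limit estimator with
deaths preceding censorings at tied times. The two-group log-rank test
sums, over distinct event times, the difference between observed events
in one stratum and the hypergeometric expectation, normalized by the
summed hypergeometric variance; no continuity correction. The
implementation is in-package because the result object reports observed
and expected events per stratum; the test suite cross-checks χ² and p
against lifelines on random cohorts and against a hand-enumerated
six-patient oracle.

## Mutation screen

Samples split into RP-mutant (≥ 1 non-silent mutation in any RP gene)
vs non-RP-mutant. For each other gene with ≥ 1 mutation anywhere, the
2×2 Pearson chi-squared statistic `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` is
computed without Yates correction; tables with an expected cell < 5 are
flagged rather than switched to an exact test. Multiplicity is
controlled by Bonferroni over the number of genes actually tested
(genes never mutated carry no information and are excluded from the
family); BH is available as an alternative. The default non-silent
whitelist covers missense, nonsense, frameshift, splice-site and
in-frame-indel classes.

## Synthetic cohorts

The generator reproduces the features of real cohorts that the
statistics rely on, and only those:

* **Baselines**: per-gene mean abundances drawn log10-uniform over
  (0, 3) — three orders of magnitude, matching the heavy spread of RP
  transcript abundance.
* **Noise**: negative-binomial counts with size parameter θ = 100
  (CV² = 1/m + 1/θ). This makes relative-expression variability rise
  automatically at low abundance — ~10% CV for abundant transcripts,
  ~100% for transcripts with mean ~1 — reproducing the observed pattern
  (most transcripts ±5–20% between normal samples, the least-expressed
  ±100–300%) without hand-tuned heteroscedasticity.
* **Tumors**: each tumor perturbs a fixed-size random subset
  (round(frac·n_genes), default 20%) of genes by a factor drawn uniform
  from 1.5–4, inverted to 1/f with probability ½. Because relative
  expression is compositional, a perturbation shifts *all* shares; the
  recorded truth is therefore the post-renormalization shift of
  expected relative expression, and the true score is the sum of its
  absolute values — the recoverable target.
* **Survival**: exponential event times with
  log-hazard = log(h₀) + β·z(score), h₀ = 10⁻³ per time unit, β = 0.5 by
  default — at β = 0.5 the planted upper/lower-quartile hazard ratio is
  ≈ 3.6. Censoring is an independent uniform U(0, c) with c solved by
  bisection so the expected censored fraction hits the target (default
  30%, the typical follow-up censoring level of the cohorts emulated).
* **Determinism**: one integer seed drives five independent substreams
  (baselines, counts, perturbations, survival, censoring) via
  `numpy.random.SeedSequence.spawn`; identical seeds give bit-identical
  cohorts.

`simulate_null_tumors` draws tumors gene-wise from Normal(μ, σ), clips
at zero and renormalizes to 100 — the calibration instrument for the
Φ-based test. Renormalization to a fixed column sum introduces a small
compositional bias in per-gene means (order σ_S²/100², where σ_S is the
SD of the raw column sum), so Monte-Carlo mean checks are posed on the
ensemble of z-scores rather than gene-by-gene; clipping is effectively
never triggered at realistic σ/μ ratios.

What the generator does **not** emulate: library-size or GC biases,
batch effects, gene-gene correlation beyond compositional coupling,
non-exponential hazards, informative censoring, and mutation
co-occurrence structure. Passing tests demonstrate the pipeline's
statistical correctness under its stated assumptions, not robustness to
those real-data complications.

## Problem sizes and reproducibility checks

The acceptance script and suite run at the sizes the statistics need
and no more: 10,000 null gene-draws for each type-I calibration (3
binomial standard errors ≈ ±0.65 percentage points), 200 tumors for
score recovery (observed Spearman ρ ≈ 0.94–0.97 across seeds), and 200
replicates of the full score → quartile → log-rank chain for power
(100% at planted HR ≈ 3.6) and null rejection (~5%). Published results
that depend on the original patient cohorts (per-cohort
significant-F-test counts, clinical survival P-values, mouse
deregulated-transcript counts) are not reproducible without those
data; the corresponding machinery is instead validated on synthetic
cohorts with known truth.

## Known limitations

* The per-transcript test assumes normality of relative expression in
  normal tissue; strongly skewed low-abundance transcripts violate this
  and real analyses exclude the worst offenders from deviation maps
  (the default exclusion list mirrors that practice).
* The cohort binomial test treats transcripts as independent;
  compositional coupling makes this approximate, which is why the
  cohort-level claim is framed as false-discovery control rather than
  an exact test.
* The score weights all genes equally in percentage points, so
  high-abundance genes dominate; this is the intended definition, not
  an artifact.
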