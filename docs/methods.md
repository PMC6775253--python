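# Methods

This note documents the statistical model behind `sdmnet`, the choices made
where the methodology was genuinely open, and the known limits of what the
synthetic experiments demonstrate.

## The measurement model

Each fish contributes one brain per time point, so every quantity is a single
observation per fish: relative expression per (region, gene), six behaviour
variables, and paired hormone samples.  qPCR relative expression is the
efficiency-corrected ratio

    x = (1 + E_hk)^CT_hk / (1 + E_gene)^CT_gene ,

evaluated in log space to avoid overflow at high cycle numbers.  CT is the
arithmetic mean of the triplicate cycle thresholds (CT averaging, not
expression averaging, is the qPCR convention for triplicates); a replicate SD
above `sd_threshold` (default 0.5 cycles) flags the value rather than dropping
it, and the screening stage decides.  Amplification efficiency is on the 0–1
scale (E = 1 is perfect doubling); config validation rejects E > 1 to catch
percent-scale inputs early.  Efficiency estimation from reaction kinetics is
out of scope — efficiencies are inputs.  The suitability of the housekeeping
reference is itself tested (one-way F across treatments on per-fish mean
*eef1A* CT); identical values everywhere give F = 0, p = 1 by convention.

## Screening and transform

Outliers are flagged with the two-sided generalized ESD (Rosner) procedure:
at step i on the n_i remaining values, R_i = max|x − x̄|/s is compared with

    λ_i = (n_i − 1) t / sqrt((n_i − 2 + t²) n_i),  t = t-quantile(1 − α/(2 n_i), n_i − 2),

and the declared outlier count is the largest i with R_i > λ_i, capped at
20% of the sample (α = 0.05).  A zero SD stops the search; n < 3 flags
nothing.  Flagged values become missing, *then* the log₁₀(x+1) transform is
applied — screening before transform matches the stated analysis order.
Screening runs within each (gene, region, treatment) cell for expression and
per variable per treatment for behaviour (a pooled option exists); the
per-treatment grouping is the conservative reading where the grouping was not
stated.  Hormone deltas are screened but not log-transformed (they are signed).

## Behaviour components

PCA is computed on the correlation matrix of the transformed variables with
loadings `v·√λ`, the convention in which the column sums of squared loadings
reproduce the eigenvalues and `λ/6·100` is the percent of variance.  With
all-numeric inputs this is also what SPSS's "variable principal normalization"
reduces to, and it reproduces the internal arithmetic of the reference loading
table exactly (Σ PC1 loadings² = 4.262 → 71.03%).  Rows with any missing
variable are excluded from the fit (listwise).  Scores are projections of the
standardized rows scaled to unit variance.  Eigenvector sign is fixed
deterministically: PC1 has a positive attack-frequency loading ("overt
aggression" scores high for fish that attack often and early), PC2 a positive
latency-to-display loading (its reflection reads as "aggressive motivation").
Latencies of fish that never performed an act are censored at the trial
duration before transform; the censoring rule is a package choice.

## Group statistics

With one observation per fish, a mixed model with a per-fish random effect is
unidentifiable, so treatment comparisons are one-way fixed-effects ANOVAs
(equivalent fixed-effect inference), run separately per response — PC scores,
each (gene, region) cell, hormone deltas.  Post hocs are two-sample t-tests
(pooled variance by default, Welch by option); the pairwise p-values of one
response form one Benjamini–Hochberg family, as do the 10 correlation
p-values of one connectivity matrix and the 21 edges of one exported network.
Cohen's d uses the pooled SD and is tabled as an absolute value; a zero pooled
SD is an explicit error, not a silent infinity.

## Network inference

Functional connectivity within a treatment is the Pearson correlation, across
fish, of (log) expression between two nuclei, pairwise-complete over missing
values; cells with fewer than three complete pairs stay missing and are
logged.  Three decisions here were open and are configurable:

- **Density** defaults to the valued definition — mean |r| over the 10 pairs —
  because published density values for such 5-node networks are not multiples
  of 1/10, which rules out edge counting; a binarized definition (fraction of
  pairs with adjusted p below a threshold) is available.
- **|r| versus signed r**: negative co-activation still constitutes a
  connection, so |r| is the default for density and centrality weights.
- **QAP null**: the standard null (no association between the matrices) is
  implemented, under which a non-significant p reads as "distinct
  co-activation patterns".

QAP correlates the 10 corresponding upper-triangle entries, permutes node
labels of the second matrix (rows and columns jointly), and reports
p = (#{|r_perm| ≥ |r_obs|} + 1)/(n_perm + 1), so p is never zero; n_perm
defaults to 5,000 and every result carries its seed.  The bootstrap density
test resamples fish with replacement within each group, rebuilds both
matrices, and refers t = Δd_obs / SE_boot to the centered bootstrap
distribution of the density difference (two-tailed, same +1 correction);
degenerate resamples (a zero-variance region) are redrawn and counted.
Eigenvector centrality is computed by power iteration on the |r| matrix with
zeroed diagonal (tolerance 1e−10, diagonal shift to guarantee convergence to
the Perron vector), oriented non-negative and scaled to unit Euclidean norm —
hence squared centralities sum to one, matching the convention of the
published per-treatment tables.  Disconnected |r| graphs are an error rather
than a silently incomparable centrality vector.

## The synthetic cohort generator

The generator's defaults are the study conditions: 8/6/6 fish (MM/MD/MS),
five nuclei, *c-fos* and *egr-1* across all nuclei plus *gnrh1* in PPa only,
triplicate CTs with 0.15 cycles of replicate noise, housekeeping CT ~
N(20, 0.25) so the reference-stability check passes by construction, and
efficiencies 0.88–0.95.  Log₁₀ expression is multivariate normal per
(treatment, gene) with a planted inter-region correlation matrix, then
converted to CTs by inverting the normalisation equation — simulating on the
log scale makes the planted structure recoverable after the pipeline's own
transform (mean log₁₀ expression 1.2 keeps x ≫ 1, so log₁₀(x+1) ≈ log₁₀ x).
The planted matrices are two-factor constructions (R = LLᵀ + diag(1−‖l‖²)),
positive definite by construction, whose implied valued densities match the
published per-treatment values (c-fos 0.56/0.36/0.54, egr-1 0.24/0.39/0.55)
and whose centrality contrasts reproduce the published qualitative pattern
(TA-central/PPa-peripheral egr-1 network in MM, the reverse in MD/MS).
Behaviour comes from a two-latent-factor model using the reference loading
pattern, with residual variance 1 − communality per variable, a −1.5 SD shift
of the overt-aggression factor in MS, truncation of frequencies at zero and
censoring of latencies at the 900 s trial.  Hormones are paired draws with a
per-fish random effect and a null treatment effect by default, matching the
study's negative androgen result.  Each generator operation draws from its
own RNG stream keyed by (master seed, operation name), so outputs are
byte-stable when operations are added.

What the generator does *not* emulate: count-valued behaviour distributions
(the latent-factor Gaussian is a modeling choice — the source analyses give no
distributional information), plate effects and melt-curve artifacts in qPCR,
assay cross-reactivity, or any fight dynamics.  Passing tests therefore
demonstrate correctness of the statistical machinery under a Gaussian
co-expression model, not robustness to those real-data features.

## Calibration findings and limitations

The evaluation experiments (`sdmnet.evaluation`, rerun by
`scripts/acceptance.py`) quantify the machinery at realistic scales:

- The QAP test is well calibrated: null rejection ≈ 0.05 at α = 0.05 over
  1000 independent matrix pairs, and Monte-Carlo p agrees with exhaustive
  enumeration of all 120 relabelings to < 0.02.
- The **bootstrap density test is structure-dependently miscalibrated at the
  study's n = 8 per group**: conservative when planted ties are near zero
  (rejection ≈ 0.006), roughly nominal for moderate planted densities
  (0.02–0.07 at densities 0.24–0.39), and anticonservative for dense planted
  structures (≈ 0.15 at densities ≥ 0.53).  Pooled over the generator's six
  planted study conditions the null rejection is ≈ 0.09.  This is a
  small-sample property of bootstrapping correlation-based statistics, not a
  bug: at n = 8 the bootstrap spread of |r| misestimates the sampling spread
  in opposite directions depending on the true tie strength.  Density
  p-values near 0.05 at these group sizes should be read with caution.
- Planted-structure recovery at n = 50/group: the lowered MS overt-aggression
  factor is recovered essentially always; the MS-densest egr-1 network is
  estimated densest in ≈ 92% of cohorts — the planted gap (0.553 vs 0.391)
  plus the upward small-sample bias of |r|-valued density (which inflates the
  sparser network's estimate more) needs ≈ 100 fish/group for 95% recovery
  and ≈ 200 for near-certainty.

Experiment sizes in the test suite and acceptance script (1000 QAP pairs at
999 permutations, 500 bootstrap replicates at 500 sub-samples, 100 recovery
cohorts at n = 50/group) were chosen to put Monte-Carlo error well below the
decision bands while keeping a full run around a minute on one CPU.

## Numerical notes

- All resampling takes explicit integer seeds; per-stage seeds derive from the
  master seed and the stage name (CRC32 XOR, kept below 2³¹), and the pipeline
  manifest records every derived seed.
- Permutation and bootstrap tail counts use a 1e−12 tie tolerance so exact
  ties count as extreme.
- Output CSVs are written with a fixed `%.10g` float format; reruns with the
  same configuration are byte-identical.
- Degenerate inputs fail loudly with named errors: constant variables in PCA,
  zero pooled SD in Cohen's d, fewer than two groups or two values per group
  in any test, non-PSD planted correlation targets, efficiencies outside
  (0, 1].
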