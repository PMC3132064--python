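# Methods

## Study design and data model

The cohort consists of `n_pairs` monozygotic twin pairs discordant for a
systemic autoimmune disease and `n_controls_per_pair` unrelated controls per
pair, matched on age (within 6 years), sex and ethnicity. Roles are P
(affected proband), U (unaffected co-twin) and C (control); a *matched set*
is one pair plus its controls and is the stratification unit for the
versus-control contrasts. Measurements are per-probe base-2 log expression
ratios (subject over a universal reference). Matching covariates are
carried in the design table and checked by a soft validator that warns on
imperfect matching but never blocks an analysis, since the estimators only
rely on the pairing/stratification structure itself.

Missing values: cells may be missing (`NA`); matched units (pairs or sets)
are dropped probe-wise when a required member is missing, group means are
missing-aware, and PCA/clustering impute a probe's missing cells with that
probe's mean. This policy is a package decision — the upstream array
processing that produced such flags is out of scope.

## Synthetic cohort generator

Per probe g and sample i,

    y[g,i] = mu_g + a[g, pair(i)] + s[g, set(i)] + h[g, batch(i)]
             + d[g, pair(i)]·(1{P} + λ·1{U}) + eps[g,i]

with mu_g ~ N(0,1) and independent zero-mean normal components. All random
effects act **per gene**: the twin-pair effect `a` (shared by the two
co-twins) models familial correlation of expression, which is a gene-level
phenomenon; the matched-set effect `s` is shared by a whole set; the batch
shift `h` is per probe × batch, because the median-centering correction is a
per-probe operation and only probe-level shifts are meaningful to it. An
alternative parameterization with a *per-sample scalar* pair effect was
considered and rejected: a scalar offset cancels identically in every
per-probe group-mean difference, contributes nothing that downstream
statistics can see, and leaves the chance intermediacy fraction at
0.5 − arcsin(1/√3)/π ≈ 0.304 (the 40-control group mean has half the
variance of the 20-sample twin groups), which contradicts the ≈1/3 rate the
design is meant to exhibit. With per-gene pair effects the twin-correlation
term pushes the chance rate toward 1/2 while the unequal group sizes push it
down, and at the default components the analytic value is ≈ 0.336.

Defaults (log2 units) and why:

| parameter | default | rationale |
|---|---|---|
| `n_pairs`, `n_controls_per_pair` | 20, 2 | the study layout (80 arrays) |
| `n_probes` | 20,000 | array size; tests use smaller matrices |
| `n_batches` | 5 | whole sets assigned round-robin, 16 samples/batch; the real batch composition is unknown, so set-coherent batches are assumed |
| `frac_de` | 0.005 | ≈ 104 significant probes of ~20,000 |
| `delta_log2` | magnitude U(0.14, 2.86), 25% up | fold range 1.1–7.2; ~3/4 of significant genes were down-regulated |
| `lambda_intermediacy` | 0.6 | mid-range transitional share; the recovery tests use this value |
| `sd_resid` | 0.4 | typical residual spread of blood two-color log ratios |
| `sd_pair`, `sd_set` | 0.3, 0.2 | familial correlation larger than matching-stratum correlation |
| `sd_batch` | 0.3 | batch shifts comparable to biological signal, making the correction consequential |
| `tail_df` | off | Student-t residuals available for heavy-tail robustness checks |

The variance-component magnitudes are calibration choices — the source
study reports none — fixed once so that the pipeline's operating
characteristics (FDR control, power, ordering enrichment) can be studied;
they are not fitted to any result. What the generator does **not** emulate:
raw two-color intensities and dye bias, probe-level measurement error
models, correlated probe blocks (co-regulated modules), or cell-composition
shifts. Passing tests therefore demonstrate correctness of the estimators
under the stated sampling model, not robustness to those real-data features.

## Estimators

**Matched contrasts.** P vs U is the paired t test on d_j = y_P − y_U
(df = n−1). P vs C and U vs C use within-set contrasts c_j = y_case −
mean(controls); the mean of c_j equals the GLS fixed effect of the
random-intercept-per-set model on balanced data because every set carries
the same design — the between-set regression has no information about the
group effect. This closed form was chosen over an iterative mixed-model fit
because it is exact, fast enough for 20,000 probes × thousands of cohorts,
and oracle-verifiable (the tests compare against a generic REML fit and
agree to ~1e-15). Degenerate inputs: a unit count below 2 or zero spread
around a nonzero effect is reported untestable (missing p); zero spread
around exactly zero yields t = 0, p = 1. Unbalanced control counts are
handled by the same contrast (the GLS equivalence then holds only
approximately; Satterthwaite-type df corrections are out of scope).

**BH-FDR.** The step-up adjustment `adj_(i) = min_{j>=i} min(1, p_(j)·m/j)`
is applied per contrast family over all tested probes, with missing p values
excluded and reinserted; selection is `adj <= q`, q = 0.1 by default.

**Intermediate ordering.** Strict betweenness `(m_U−m_P)(m_U−m_C) < 0`;
ties count as not intermediate (they have measure zero on continuous data).
Means are taken on the batch-centered matrix, the same data used for
testing. The chance reference is 1/3 (two of six orderings of exchangeable
means); because twins are correlated and group sizes differ, the exact
chance probability deviates slightly (≈ 0.336 under the generator
defaults), so reports show the observed genome-wide fraction alongside 1/3
rather than asserting exact equality. Enrichment over a subset uses the
exact binomial upper tail at p0 = 1/3. The permutation null reassigns the U
label uniformly within each set's {twin, controls} pool with probands
fixed, and recomputes the fraction; `p = (1+#{perm >= obs})/(1+n_perm)`.
This null is well calibrated when U is exchangeable with C, but it has low
power against pure intermediacy: a group mean mixing true co-twins with
controls is itself intermediate, so many permuted configurations tie with
the observed statistic. The binomial test is the primary enrichment
measure; the permutation p is a check of U/C exchangeability.

**λ recovery.** The intermediacy coefficient is estimated over truly
affected probes by the regression-through-origin ratio
Σxy/Σx² with x = m_P − m_C and y = m_U − m_C. The plain average of
per-probe ratios is also provided but is only reliable in low-noise
regimes: when a disease effect is small relative to group-mean noise the
denominator can change sign and the ratio explodes.

**Subtype tests.** One-way ANOVA with explicit degenerate handling (groups
with <2 observations dropped; <2 groups untestable; all-constant data gives
F = 0, p = 1; zero within-group spread with distinct means gives F = ∞,
p = 0). The status × subtype interaction under a random-intercept-per-set
model reduces, on balanced data, to the same ANOVA applied to the
within-set contrasts; this keeps both subtype analyses on one verified code
path.

**Clustering.** Distance 1 − Pearson correlation over the probe subset and
average linkage by default (the common choice for expression heat maps;
Euclidean/complete are switches). Constant sample profiles get correlation
distance 1 to all others, with a warning. Merging is delegated to scipy's
agglomerative linkage; on tied distances its deterministic internal order
applies (ties have measure zero on continuous data). Dendrograms serialize
to Newick; the two-branch membership comes from the root split, with branch
1 anchored at the lexicographically smallest sample id for determinism.

**qPCR concordance.** RQ = 2^(−ΔΔCt) with GAPDH normalization; "same
trend" means sign agreement with both signed-fold magnitudes ≥ 1.1. The
1.1 floor operationalizes "no difference detected" for near-unity folds and
reproduces the validation panel's two exceptions (a sign flip and a
1.02-fold qPCR result); it is a configurable decision, validated only
against that panel.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds recorded in
the run manifest; identical config + seed reproduces every artifact
byte-for-byte (fixed 6-decimal TSV formatting, `NA` missing token). Batch
medians use the midpoint convention for even counts. The pipeline writes
TSV/Newick/JSON only; plotting is left to external tools.

## Problem sizes in the test suite

The suite exercises the same code paths as a full-size run at reduced
scale, chosen as the smallest sizes at which each statistical property is
decisively measurable: FDR control over 50 cohorts of 2,000 probes; the
chance-intermediacy fraction on one 20,000-probe null cohort; λ and effect
recovery on 5,000-probe cohorts (three replicates) and 200-pair cohorts
(five replicates, Monte-Carlo averaging of the bias); null calibration with
probes as replicates (1,000) and 500 permutation replicates of 250 probes.

## Known limitations

* The within-unit contrast estimators are exact GLS only for balanced
  designs; strongly unbalanced sets lose a little efficiency and the
  mixed-model equivalence becomes approximate.
* Genome-wide FDR control is proven for independent or positively dependent
  tests; the generator draws probes independently, and real co-expression
  structure is not emulated.
* The permutation enrichment test has low power against intermediacy per
  se (see above).
* No empirical-Bayes variance moderation: with only 20 pairs, per-probe
  variance estimates are noisy, and small-|δ| probes are under-powered —
  consistent with the motivating analysis, which likewise tested probe by
  probe.
* Probe→gene annotation, GEO parsing, and pathway-database content are out
  of scope; category enrichment takes user-supplied gene→category tables.
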