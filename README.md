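# twindiff

Matched twin-pair differential expression analysis for blood transcriptome
cohorts of monozygotic twins discordant for systemic autoimmune disease
(SLE, RA, or idiopathic inflammatory myopathy).

## The problem

In a discordant-twin design, each twin pair consists of an affected proband
(P) and their unaffected co-twin (U); every pair is matched to unrelated
healthy controls (C, two per pair) on age, sex and ethnicity, forming a
*matched set*. Expression is measured per probe as the base-2 log ratio of a
subject's RNA over a universal reference on two-color arrays. The analysis
asks three questions:

1. which probes are differentially expressed between probands and matched
   controls (and in the two other comparisons, P vs U and U vs C), while
   respecting the twin pairing and the matched-set stratification;
2. whether unaffected co-twins occupy a *transitional* state: is the U group
   mean strictly between the P and C means more often than the chance rate
   of 1/3, in particular among the significant probes;
3. whether any of it is disease-subtype specific.

## The statistics

* **Batch correction** — per probe, the median within each hybridization
  batch is subtracted, so every (probe, batch) block has median 0; PCA of the
  samples serves as the before/after diagnostic.
* **Matched contrasts** — for P vs U, the paired t test on within-pair
  differences d_j = y_P − y_U; for P vs C and U vs C, a t test on the
  within-set contrasts c_j = y_case − mean(controls in set j). On balanced
  data these are exactly the generalized-least-squares fixed-effect estimates
  of the corresponding random-intercept mixed models (verified against a
  generic mixed-model fit in the tests). Each genome-wide family of p values
  is adjusted by the Benjamini–Hochberg step-up procedure (FDR target 0.1).
  Effects are displayed as signed folds: 2^d for d ≥ 0, −2^(−d) otherwise.
* **Intermediate ordering** — per probe, the event
  (m_U − m_P)(m_U − m_C) < 0; its fraction over a probe set is compared with
  the chance value 1/3 by an exact binomial tail and, optionally, by a
  within-set permutation null that reassigns the U label among each set's
  twin and controls.
* **Subtype tests** — a three-category one-way ANOVA of within-pair
  differences across diagnoses, and the status × subtype interaction as the
  same ANOVA applied to within-set contrasts, both BH-adjusted.
* **Validation** — ΔΔCt relative quantification (RQ = 2^(−ΔΔCt) after
  reference-gene normalization) and trend concordance between qPCR and
  microarray signed folds (same sign, both magnitudes ≥ 1.1).

A synthetic cohort generator (`twindiff.simulate`) reproduces the design —
20 pairs, 2 controls each, ~20,000 probes, per-gene twin-pair/matched-set/
batch/residual variance components, a minority of probes carrying disease
effects of 1.1- to 7.2-fold, and an intermediacy coefficient λ giving the
share of each effect expressed in the unaffected twin — with ground truth
for recovery tests, so the whole pipeline runs without any download.

## Worked example

```python
from twindiff import (SimParams, simulate_cohort, median_center,
                      MatchedContrastTest, IntermediateOrdering)

params = SimParams(n_probes=5000, frac_de=0.02, lambda_intermediacy=0.6, seed=42)
matrix, design, truth = simulate_cohort(params)
normalized = median_center(matrix, design)

test = MatchedContrastTest(contrast="PvC", fdr_q=0.1).fit(normalized, design)
selected = test.selected_probes()
print(f"probes selected at FDR 0.1: {len(selected)}")

ordering = IntermediateOrdering(probe_subset=selected).fit(normalized, design)
r = ordering.result_
print(f"intermediate ordering: {r.k}/{r.n} = {r.fraction:.2f} "
      f"(chance 1/3, binomial p = {r.p_binomial:.2e})")
```

prints

```
probes selected at FDR 0.1: 96
intermediate ordering: 96/96 = 1.00 (chance 1/3, binomial p = 1.57e-46)
```

i.e. 96 of the 100 truly affected probes reach significance, and for the
selected probes the unaffected twins' mean lies between probands and
controls essentially always — far above the genome-wide fraction (0.348 in
this run), reproducing the qualitative signature of a transitional state.

A command-line interface exposes the same stages
(`twindiff simulate | normalize | test | order | subtype | cluster |
concordance | run-all`); `twindiff run-all --seed 7 --out run/` writes every
report as TSV/Newick plus a manifest with per-artifact checksums, and is
byte-reproducible for a fixed config and seed.

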