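# Methods

## Model and assumptions

`sexsig` treats sex-biased drug-response prediction as a two-stage set
association problem.

**Stage 1 — sex-biased genes.** Expression values are assumed to be
approximately Gaussian per gene on the log2 scale within each sex, with the
male/female difference captured by a mean shift. Each gene is tested with a
two-sided two-sample t-test; Welch's unequal-variance form is the default
because microarray variances are rarely equal across groups, and the pooled
form is exposed for comparison (with balanced group sizes and equal
variances the two statistics coincide, which the suite checks to 1e-9).
Multiplicity across genes is handled by Benjamini–Hochberg; the FDR cut
(q ≤ 0.05) is the sole criterion for calling a gene male-biased (MG,
log2 FC > 0) or female-biased (FG, log2 FC < 0). A minimum fold-change
criterion exists but defaults off: fold change is reported for
interpretation, not used as a filter. Cohort balance on age can be checked
with a two-sided Wilcoxon rank-sum test (exact enumeration up to 20 per
group without ties, tie-corrected normal approximation otherwise).

**Stage 2 — drug association.** A drug's transcriptional footprint is the
pair (UG, DG) of genes whose treatment/control fold change crosses ±2.0 on
the signed linear scale (r for r ≥ 1, −1/r for r < 1; equivalently
|log2 FC| ≥ 1 — the two thresholds are proven equivalent in the suite).
Independence of "sex-biased" and "drug-regulated" is tested per drug by
Fisher's exact test on the 2×2 table over the shared gene universe. The
headline statistic uses the pooled sets (MG ∪ FG vs UG ∪ DG); the four
directional tables are always computed and reported so that
direction-specific structure (e.g. a drug up-regulating specifically
female-biased genes) remains visible. Two-sided p-values follow the
conventional definition — the sum of probabilities of all margin-preserving
tables no more probable than the observed one, with a 1+1e-7 relative
tolerance on the comparison. The odds ratio reported is the sample OR
(a·d)/(b·c), with Haldane's 0.5 continuity correction applied (and flagged)
only when a cell is zero; a conditional-MLE OR is deliberately not used, as
the ranking depends only on p.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `fdr_threshold` | 0.05 | — | standard FDR level for calling sex bias |
| `up_min` / `down_max` | 2.0 / −2.0 | signed linear FC | conventional two-fold signature cut |
| `t_variant` | welch | — | robust to unequal group variances |
| `alternative` | two_sided | — | no prior direction for an association |
| `universe_policy` | intersection | — | per-drug universe = tested ∩ measured genes, preventing inflation from genes one side never saw |
| `top_n` | 20 | drugs | screening-report convention |

## Design choices where the design was open

- **Universe policy.** Counting genes that only one data source measured
  would inflate cell d and shrink p artificially; the per-drug intersection
  is the honest margin. The `expression_side` policy is kept for
  sensitivity analysis.
- **Ranking ties.** (p ascending, odds ratio descending, drug id) makes
  reports deterministic; BH q-values across drugs are reported alongside
  raw p because a screen of ~1,000 drugs needs multiplicity control even
  when only a top-20 list is published.
- **Missingness.** A gene is dropped when more than 20% of either sex's
  samples are missing; remaining missing values are ignored pairwise.
  Genes with zero variance in both groups are excluded (no defined t);
  zero variance in a single group keeps a finite Welch statistic and is
  retained.
- **Linear-scale input** is log2-transformed after adding a pseudocount
  (default 1.0); matrices are assumed log2 unless declared otherwise, the
  convention for normalized microarray series.
- **Probe collapse** keeps the probe with greatest mean expression
  (`max_mean`, the common microarray convention) or takes per-sample
  medians; ties go to the first probe in file order for determinism.

## The synthetic-data generator

The generator emulates exactly the structure the analysis assumes: per-gene
log2 values are Normal(baseline 8.0, sd 0.5) i.i.d. across samples, planted
MG/FG genes add a +1.0 log2 shift to the favoured sex's mean, and drug
signatures are gene sets sampled without replacement from the measured
universe — uniformly for null drugs, and with round(assoc_fraction · size)
genes taken from the planted sex-biased pool for associated drugs. The
default study — 2,000 genes, 40+40 samples, 50+50 planted genes, 1,000
drugs of 100+100-gene signatures with 20 associated drugs at
assoc_fraction 0.5 — gives per-gene effects of two noise SDs (t ≈ 9 at
n = 40 per sex, essentially full power) and planted overlaps (a ≈ 100)
that dominate null overlaps (a ≈ 10), so recovery failures indicate real
defects rather than borderline power. Signature sizes of ~100 genes per
direction match what a two-fold cut typically yields on perturbation
profiles. A single NumPy Generator stream drives all draws, so one seed
reproduces an entire study; `heteroscedastic_sd_jitter` adds lognormal
per-gene variance spread for robustness checks, and an optional emitter
produces synthetic fold-change tables (signature genes near ±4-fold,
background near 1-fold with lognormal jitter) to exercise the thresholding
path.

What the generator does **not** emulate: gene–gene correlation, mean–
variance trends, batch structure, heavy-tailed noise, or any biological
relationship between a drug's signature and expression levels. Passing
tests therefore demonstrate correctness of the statistics and plumbing
under the model's own assumptions, not performance on real cohort data,
where correlated genes make effective test counts smaller and FDR control
approximate.

## Calibration protocol

Null calibration (no planted effects, no planted associations) cannot use
the FDR-thresholded MG/FG sets — under the null they are empty and the
association stage correctly refuses to run. The calibration protocol
instead takes genes at raw p ≤ 0.05 (expected ~5% of the universe) as the
sex-set stand-in; under the null this selection is independent of the
signature draws, so the association p-values retain their null
distribution. Measured this way, the fraction of drugs at p ≤ 0.05 runs at
≈ 0.034–0.049 rather than 0.05: Fisher's exact test is discrete and
conservative, and exact enumeration over the realized margins (universe
2,000, sex set ≈ 100, regulated set 200) shows this is the test's true
attainable level, not an implementation artifact. The null fraction
therefore never exceeds its nominal level plus binomial noise, but can sit
meaningfully below it — the direction of error that protects against false
drug calls.

## Numerical and procedural details

- BH adjustment is computed via statsmodels (`fdr_bh`) behind the package's
  own validated surface; the suite checks it elementwise against a
  brute-force step-up evaluation to 1e-12.
- Fisher p-values come from scipy's exact implementation; the suite checks
  them against an exact-rational (integer arithmetic) hypergeometric
  enumeration on every table with universe ≤ 40, to 1e-10.
- p-values are clamped to (0, 1] so downstream BH validation never sees an
  exact zero from floating-point underflow.
- Report floats are written at six significant digits; expression matrices
  round-trip at full precision (`%.17g` plus round-trip float parsing).
- Pipeline outputs contain no timestamps, so a fixed config and seed
  reproduce byte-identical TSVs.
- Test problem sizes: exhaustive Fisher checks stop at universe 40
  (≈ 136k tables), calibration and recovery checks use the default study
  over 20 fixed seeds; these sizes give the properties room to fail while
  keeping the suite's total runtime a few minutes.

## Known limitations

- Probe-to-gene mapping must be supplied; no platform annotation is
  bundled.
- The association test treats genes as exchangeable; correlated genes
  (pathways, chromosomal clusters, sex-chromosome blocks) violate the
  hypergeometric sampling model and make real-data p-values optimistic.
- Replicate aggregation for multi-instance perturbations is a linear-scale
  mean (median optional); no instance-level quality weighting.
- The clinical summary-statistics t-test assumes the printed mean/SD/n
  fully describe each group; it cannot model pairing or covariates.
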