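# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limits of what the bundled studies can
show.

## The linking model

### Discovery scan

Discovery regresses each protein on each SNP's minor-allele dosage
(0/1/2) under an additive model with no covariates, using simple OLS and
a two-sided t test on the slope. Protein values are rank-based inverse
normal (rank-INT) transformed per column before the scan:

    x ← Φ⁻¹((rank − c) / (n − 2c + 1)),   c = 3/8 (Blom offset)

with average ranks for ties. Rank-INT makes the scan robust to the heavy
right tails of relative-fluorescence abundances; the Blom offset is the
common default in the pQTL literature and is exposed as a parameter.
SNPs enter the scan only when their sample MAF is *strictly* greater
than the threshold (default 5%), with missing calls excluded from the
MAF denominator rather than imputed.

Associations are kept at Benjamini–Hochberg FDR < 0.05, applied within
each cohort's full SNP×protein scan (cohorts are scanned independently
and merged afterwards). The significant set is reduced to a perfect 1:1
protein↔SNP matching in two passes: per protein keep the single
smallest-p record (conflicts across cohorts resolved by smallest p),
then per remaining SNP keep the single smallest-p record. p-value ties —
possible in principle, common in tests — break by larger |t|, then
lexicographic (protein, SNP) ids, so reduction is deterministic.

### Genotype inference and matching

For each panel pair the model is a three-class Gaussian naïve Bayes on
the **natural-log** protein level x (discovery uses rank-INT, estimation
uses log — two transforms, one pipeline):

* class-conditional density N(x; μ_g, σ_g), with μ_g, σ_g the sample
  mean and SD (n−1 denominator) of x among training subjects with
  dosage g;
* class prior P(g) = empirical training class frequency;
* posterior P(g|x) ∝ P(g)·N(x; μ_g, σ_g), normalized over the classes
  present in training.

The model stores per-class sufficient statistics (count, Σx, Σx²), so
training on a second cohort pools the statistics and reproduces the
single-pass fit on the concatenated data exactly — useful when cohorts
cannot be co-located.

A candidate genome g₁…g_N scores the sum over panel pairs of the log
odds of its dosages:

    score(genome) = Σᵢ [ log P(gᵢ|xᵢ) − log(1 − P(gᵢ|xᵢ)) ]

equivalently the log of the product of per-pair odds. Candidates are
ranked by score (ties broken by genome id); accuracy is reported as the
fraction of proteomes whose true genome ranks first (top-1), within
three (top-3), and within the top 1% window (window =
`ceil(0.01·n_genomes)`, minimum 1; `floor` is available as an option
since the rounding convention is genuinely ambiguous for this summary).

### Numerical choices

* All odds arithmetic is in log space; a raw product of ~100 odds
  under/overflows double precision.
* Posteriors are clipped to [1e-12, 1−1e-12] before the odds transform,
  which bounds any single pair's contribution at ±log(1e12) ≈ ±27.6 and
  guarantees finite scores.
* σ floor: σ_g = max(sample SD, 1e-6 × pooled SD of the pair), so a
  class whose observed values are constant cannot produce a degenerate
  delta density.
* Degenerate classes (count < 2, default) fall back to the pooled SD of
  the pair; a class with count 0 receives prior 0 and is excluded from
  the posterior's support — absent evidence is not invented. (An
  HWE-derived prior would be a reasonable alternative for unseen
  classes; empirical priors are the default because they reproduce the
  standard incremental GaussianNB behaviour.)
* A genome's missing dosage at a pair skips that pair (contributes 0).

## Privacy defense

Genotype-mean adjustment removes each panel protein's class mean on the
log scale and recenters on the grand mean:

    x′ = x − μ_g + μ̄,    μ̄ = Σ_g (count_g · μ_g) / Σ_g count_g

Recentering keeps the published values on the original scale (bare
subtraction is available via a flag). Reference means default to the
same model used for linking — the defense assumes the attacker's model —
with self-estimated means supported for publishers without the training
model. The per-class corrections are emitted as a table; holders of the
genotypes invert the adjustment exactly (round-trip error at machine
precision), and a state flag prevents accidental double adjustment or
double reversal. Proteins outside the panel are never touched, which is
why phenotype associations carried by non-genetic variance survive.

The association check is a per-protein Welch two-sample t-test on log
values (unequal variances; the more conservative default when group
variances differ). Note one intrinsic caveat: adjustment removes the
genotype component of a protein's variance, so the post-adjustment t
statistic of a *preserved* association still grows by roughly
√(1 + β²·varG/σ²). For strong pQTLs (β ≈ σ) that is a mechanical ~20%
inflation; the preservation study therefore uses moderate effects
(β = 0.25, ≈2.6% of variance — typical of rank-and-file pQTLs) where the
change stays within a few percent. This is a property of variance
removal, not an artifact of the implementation.

## Identity analyses

**Proteome-to-proteome.** Serial proteomes of one subject are matched by
Euclidean distance over the panel proteins on the log scale, by default
z-scored with reference-set statistics so high-variance proteins do not
dominate the metric.

**Relatives.** A sibling shares ~half of each parent's transmitted
alleles, so a sibling's genome ranks far above unrelated genomes in the
odds ranking without ranking first. The summary reports the fraction of
subjects with at least one — and with all — sibling genomes inside the
top-1% window.

**Mislabel diagnosis.** Subjects with multi-visit proteomes are linked
per visit; classification uses only *confident* mismatches, where the
top genome is not the subject's own and its softmax posterior over the
candidate set is ≥ θ (default 0.99). The gate matters: a mislabeled
sample matches the wrong genome with near-certain posterior, while a
noise-induced link failure sits near the decision boundary (posteriors
~0.9 in simulation), and treating those as evidence would flag clean
subjects. Rules:

* every visit confidently mismatches to the same wrong genome, ≥2
  visits → DNA mislabel (mirror-image patterns merge into one
  reciprocal event);
* exactly one of ≥2 visits mismatches, with the reciprocal confident
  mismatch in a second subject at the same visit → plasma swap;
* anything else, including any confident mismatch by a single-visit
  subject → indeterminate. Single-visit cases are undecidable by
  design: nothing distinguishes a mislabeled proteome from a mislabeled
  genome.

The tool proposes corrections; it never rewrites inputs.

## Synthetic cohort generator

The generator produces exactly the structure the model assumes:

* **Genotypes**: independent biallelic SNPs in Hardy–Weinberg
  equilibrium, dosage = minor-allele count, per-SNP (optionally
  per-population) MAF. No linkage disequilibrium — the reduced panel is
  1:1 by construction, mirroring post-pruning panels.
* **Proteins**: log-abundance = baseline + β·dosage + N(0, σ);
  emitted on the raw (exponentiated, strictly positive) scale so the
  log-transform step is exercised. Defaults in the bundled studies:
  β = 1, σ = 1, MAF ~ U(0.1, 0.5), 100 pairs — a strong-pQTL panel.
  Baselines are drawn from U(6, 9) on the log scale (e⁶–e⁹ spans
  typical relative-fluorescence magnitudes); they do not affect
  separability.
* **Visits**: each subject has a stable latent level (baseline +
  genotype effect + N(0, σ)); visits add independent N(0, 0.3σ) noise,
  so serial proteomes are mutually nearest while remaining imperfect.
* **Families**: HWE parents, Mendelian transmission (each parent
  transmits the minor allele with probability dosage/2), ≥2 offspring.
* **Phenotype**: Bernoulli(prevalence) case status independent of
  genotype; affected proteins shift by a constant on the log scale in
  cases.
* **Label errors**: a plasma swap exchanges two subjects' proteome rows
  at one visit; a DNA mislabel exchanges two subjects' genotype rows
  persistently (a chain-of-custody tube swap — the exchange is what
  makes the observed "all visits map to another person's genome"
  pattern possible). The injection ledger is the ground truth for
  diagnosis tests.

Randomness: one master seed; every operation draws from a substream
keyed by (operation, SNP-or-protein id), so enlarging a panel never
perturbs existing draws, and every function is a pure function of
(inputs, seed).

### What the generator does not emulate

Real panels have LD between SNPs, correlated proteins (shared pathways,
assay cross-reactivity), batch and plate effects, non-Gaussian residuals
after log transform, population admixture beyond discrete labels, and
imputation uncertainty. Passing studies therefore demonstrate
correctness of the algorithms under the model's own assumptions and
realistic effect sizes — not field performance on any particular
platform. Upstream assay normalization is treated as done; inputs are
assumed normalized abundances.

## Bundled studies and their scale

The canned studies (`protlink.studies`, also driven by
`scripts/acceptance.py`) use desk-scale versions of the real workflow,
chosen to finish in seconds while keeping the statistics meaningful:

* two training cohorts of 1184 and 1028 subjects (the sizes of the
  original discovery cohorts), independent discovery per cohort, merged
  reduction, incremental training;
* an independent 500-subject test cohort (candidate set of 500 genomes,
  chance = 0.2%);
* 100-pair strong-effect panel (β = σ = 1). At these conditions the
  odds-product matcher's intrinsic top-1 accuracy — measured with the
  *true* generative parameters, no estimation error — is ≈0.92–0.93,
  consistent with the 90–95% regime reported for kilo-protein panels;
  top-1% accuracy is ≈0.99;
* the swap-diagnosis study uses a 300-pair panel: mislabel diagnosis
  presumes per-link accuracy near 100%, the regime of the densest
  platforms, and at 100 pairs intrinsic link errors would dominate the
  three injected events;
* the association-preservation study uses β = 0.25 (see above), a
  log-scale shift of 1.0 in half the cohort, n = 1000;
* sibling detection: 60 three-offspring families among 440 unrelated
  genomes, model trained on a separate cohort.

## Known limitations

* The defense is tailored to mean-based (naïve Bayes) profiling;
  higher-moment or multivariate attacks are out of scope, as are
  differential-privacy-style obfuscation schemes.
* Genotype-mediated phenotype associations are attenuated by the
  adjustment — by design, the genetic signal is what gets removed.
* Sex chromosomes, non-biallelic variants, and covariate-adjusted
  discovery models are not supported.
* The diagnosis rules require multi-visit data to classify an event;
  single-visit mismatches are reported but never resolved.
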