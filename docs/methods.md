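# Methods

## Pathway-activity model

The scoring model for each signalling pathway is a two-layer Bayesian
network. The hidden node is a binary pathway state `A` (the pathway's
transcription factor actively driving transcription or not). The observed
nodes are one binary evidence variable per target gene,
`E_g = [x_g > c_g]`, where `x_g` is the gene's log2 expression and `c_g` a
frozen discretization cutoff. Genes are assumed conditionally independent
given `A` (naive-Bayes structure), so the posterior factorises into a
product of per-gene likelihood ratios on the prior odds. The probe layer of
array-based formulations is deliberately absorbed into the per-gene
discretization: the package consumes gene-summarised matrices, so per-gene
binary evidence is the natural granularity.

**Calibration** (`calibrate_model`) requires a training cohort of a single
cell type with at least two samples labelled `active` and two `inactive`.
Per gene:

* cutoff `c_g` = median of the gene's values over *all* training samples
  (both classes pooled). The median is the simplest cutoff rule that can be
  frozen with the model and applied unchanged everywhere else;
* `P(high | active)` and `P(high | inactive)` = Laplace-smoothed frequencies
  of `x > c_g` within each class, `(k + α) / (n + 2α)` with pseudocount
  `α = 1` by default. Smoothing keeps every conditional probability strictly
  inside (0, 1), so no single gene can contribute infinite odds;
* genes missing from the training matrix, or with identical values in every
  training sample (degenerate cutoff), are dropped with a logged warning.

The returned model is **frozen**: a frozen dataclass with read-only
parameter maps. Scoring never mutates it, and a sample's score depends only
on its own column — re-scoring after extending a cohort leaves earlier
scores bit-identical.

**Scoring** (`score_sample`) accumulates log2 likelihood ratios; genes
absent from the sample contribute a ratio of 1 and are listed in
`missing_genes`, while a sample sharing *no* genes with the model raises an
error rather than silently returning the prior. Down-regulated target genes
go through the same machinery — their calibrated `P(high | active)` simply
ends up below `P(high | inactive)`; there is no sign flip in code. The
reported log2 odds is clamped to ±60. Near the clamp the companion
posterior probability saturates to 0/1 in double precision (the
probability/odds identity is exactly representable only up to roughly ±50
log2 units); the log2-odds value is the primary scale and is exact.

The default prior is `P(active) = 0.5` (zero prior log2 odds). The prior is
a reporting convention, not a biological claim: a negative score means
evidence against activity relative to an uninformative prior, **not** that
the pathway is off. Interpretation rules honoured throughout the package:
scores are never compared across pathways on a raw scale (each pathway has
its own range); comparisons are within-pathway across samples; scores are
kept at full precision until report rendering (3 decimals for p-values).

**PI3K inverse inference** (`infer_pi3k_from_foxo`): PI3K activity is read
qualitatively from FOXO transcription-factor activity relative to a
reference sample — higher FOXO ⇒ lower PI3K — and is only valid without
cellular oxidative stress, which activates FOXO independently of PI3K; with
stress (or a tie) the call is `indeterminate`. FOXO is always reported as
FOXO, never relabelled as a PI3K score. Only the qualitative call is
implemented; a quantitative inversion would need a validated mapping between
the two scales.

## Sample QC

QC is a rule engine over a per-sample metrics table (not CEL files — the
probe-level inputs those require are out of scope): average probe intensity,
counts of negative and >16-bit values, poly-A and labelled-cRNA spike-in
flags, GAPDH and ACTB 3′/5′ ratios, centre of intensity, positive/negative
border-control means, and an RNA degradation slope (OLS slope of mean
intensity against probe-position index — calculators are provided for the
two metrics derivable from probe-summary inputs). Default bounds follow
common Affymetrix guidance: 3′/5′ ratios ≤ 3, zero negative and zero
overflow values, spike-ins required true, degradation slope in (−1, 4).
For the scale-dependent metrics (average intensity, centre of intensity,
border means) `cohort_relative_rules` sets mean ± 3 SD bounds from the
cohort itself; fixed fall-back bounds are also provided. Every rule is
individually configurable and can be disabled — the guidance literature
bundles the parameters differently (the canonical "12 parameters" count
groups some pairs), so the rule set is data, not code. `evaluate_qc` is a
pure function and rule-order independent; `filter_cohort` preserves sample
order and logs removals.

## Cohort analysis

* `normal_threshold`: upper bound of the normal range = mean + k·SD of
  healthy reference scores (default k = 2, sample SD with n−1 denominator;
  the "mean ± 2SD" convention is read as a one-sided *upper* bound since
  abnormality of interest is elevated activity). `classify_abnormal` uses a
  strict `>` — a score exactly at the threshold is normal.
* `mann_whitney`: U counted with mid-ranks; the p-value is exact (full
  enumeration-equivalent null distribution over the C(n1+n2, n1) labelings)
  when n1+n2 ≤ 20 with no ties, otherwise the normal approximation with
  continuity and tie correction. The `alternative` is always explicit; small
  printed p-values like 0.028 at 5 vs 5 correspond to the exact one-sided
  tail 7/252.
* `wilcoxon_paired`: zero differences dropped (count logged; all-zero input
  degenerates to p = 1 with a warning); exact 2^n sign-pattern p for n ≤ 15
  nonzero untied differences, else normal approximation with continuity
  correction.
* `pearson`: r with the two-sided t-transform p (n−2 df); zero variance is
  an error.
* `match_profile`: similarity of a sample to labelled reference profiles =
  Pearson correlation of per-pathway **standardised** scores, centring and
  scaling each pathway by the pooled reference set's mean and SD so no
  pathway's wider log2-odds range dominates. References are ranked by
  similarity, ties broken by label order. At least two shared pathways are
  required.
* No multiple-testing correction enters any verdict; a Bonferroni-adjusted
  column is emitted in comparison reports for transparency only.

These are standard statistics and are delegated to scipy behind this
module's interface; the test suite checks them against independent
brute-force enumeration oracles.

## Synthetic-data generator

The generator emulates the *structure* of CD4+ T-cell subset studies, not
any real dataset. Scenario specs carry a per-pathway activation level
`a ∈ [0, 1]`; target gene `g` (direction `d = ±1`) in a sample with
activation `a` is drawn as `mu_g + d·Δ·a + ε`, `ε ~ N(0, σ²)`, with per-gene
baselines `mu_g ~ N(7, 1)` log2 units (a typical mid-range array intensity)
drawn once per cohort. Defaults Δ = 2 log2 units and σ = 0.5 describe a
strong, clean in-vitro contrast; recovery benchmarks use the harder σ = 1.
σ = 0 gives the exact noise-free limit. Background genes (baseline + noise
only) exercise gene-set lookup and missing-gene paths. Randomness is
numpy's PCG64 seeded once per cohort with a documented draw order
(baselines, then per sample: mixture fraction, noise vector), so output is
bit-reproducible for a given spec + seed.

Preset activation levels encode the qualitative orderings observed for the
cell states (activation raises NFκB/JAK-STAT1/2/JAK-STAT3 and lowers FOXO
and TGFβ; Th1 vs Th2 contrasts; the suppressive iTreg state with high NFκB,
JAK-STAT3, TGFβ, Notch; supernatant-treated activated cells with the
reverted, TGFβ-high profile). The *orderings* are the anchored claims; the
numeric `a` values and the patient-mixture Treg fractions (blood 0.15–0.35,
lymph node 0.30–0.50, tumour infiltrate 0.60–0.90, mixed toward the iTreg
vector per sample) are illustrative choices, since the underlying fractions
are not quantified. QC tables plant failures only on fixed-bound metrics,
at least 5 bound-widths out, so planted failures are unambiguous and
cohort-relative bounds stay uncontaminated.

What passing tests on this generator shows — and does not. The generator has
no probe-level structure, batch effects, cross-pathway transcriptional
crosstalk, or heavy-tailed noise; conditional independence of genes given
the pathway state holds *by construction*, matching the scoring model's
assumption. Recovery results (AUC, sign patterns) therefore demonstrate the
machinery's correctness, not real-data performance, and the absolute
log2-odds values of proprietary calibrated assays on real arrays are
explicitly not reproduced.

## Numerical and design choices

* Binary evidence makes scores discrete: samples with identical evidence
  patterns score identically, so exact rank tests on scores of small strongly
  separated groups can hit ties; the statistics flag `ties_present` and fall
  back to the approximation by policy.
* Clamp at ±60 log2 odds; pseudocount default 1; prior default 0.5.
* Thresholds: strict `>`; SD with n−1; k configurable.
* Model files are JSON with full float repr (bit-exact round trips);
  expression TSVs round-trip to 6 significant digits; all writers stamp
  version/seed/config-hash comment headers that all readers skip.
* Calibration metadata records class sizes, pseudocount and a content hash;
  no wall-clock timestamp, keeping pipeline outputs byte-deterministic.
* The CLI `run-all` calls the same stage functions as the individual
  subcommands, so composed and stage-by-stage runs are bit-identical.

## Known limitations

* Qualitative PI3K call only; no quantitative FOXO inversion.
* QC consumes precomputed metric tables; it does not parse CEL files or
  reimplement affyQCReport/AffyRNAdeg internals.
* Binary (median-cutoff) discretization only; no multi-level or continuous
  evidence.
* Healthy-donor thresholds are always recomputed from supplied or simulated
  references — none are hard-coded.
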