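# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Cohort model and truth labels

A nodule carries a cytological category (TIR3A or TIR3B), a histological
diagnosis (FA, FV-PTC, NIFTP), a BRAF/RAS mutation status and an
instrument QC flag.  Histology defines the diagnostic truth: FA is benign;
FV-PTC and NIFTP are malignant (NIFTP requires surgical excision, so for a
rule-out test it must not be missed).  The package ships the aggregate
composition of a 98-nodule cohort (cell counts over cytology × histology ×
mutation) that can be expanded into a per-sample annotation table; its
cross-tabulation and the mutation marker's 2×2 performance are recomputed,
never stored.

Reported percentages use half-up rounding to one decimal.  The mutated
fraction 32/98 is 32.653%, which rounds to 32.7%; the unrounded fraction
is always available from `CrossTab.fraction`.

## Normalization and filtering

Digital counts are normalized per sample to the arithmetic mean of the
top-k (default 100) endogenous counts: `factor_i = mean_j(m_j) / m_i`.
After normalization every sample's top-k mean equals the grand mean by
construction (asserted to 1e-9 relative).  Control probes never enter
normalization, filtering or PCA.  Background subtraction from negative
controls is out of scope (instrument software territory).

The expression scale is `log2(normalized count + 0.1)`.  The offset is
added *before* the logarithm: the alternative reading ("add 0.1 to the
log2 counts") cannot prevent log of zero, which is the offset's stated
purpose.  An offset parameter exposes the magnitude.

The filter keeps a miRNA if its mean log2 expression strictly exceeds 4
(rule a), or, failing that, if its unbiased sample variance is at least
1.5 × its own mean log2 expression (rule b).  Two readings of rule b's
reference value exist; the literal antecedent (the miRNA's own mean) is
the default and `var_reference="mean_variance"` gives the alternative.
The threshold comparison for rule a is strict; boundary behaviour is
covered by a test.  Arithmetic means are used throughout.

## Moderated differential expression

The two-group comparison is wild-type FA (baseline) versus wild-type
FV-PTC; mutated samples and NIFTPs are excluded from fitting and enter
only at scoring time.  Per miRNA the pooled variance s² on
d = n1 + n2 − 2 degrees of freedom is shrunk toward a prior s0²:

    s_post² = (d0·s0² + d·s²) / (d0 + d)
    t = (mean_case − mean_baseline) / (s_post · sqrt(1/n1 + 1/n2))

with P from a t distribution on d0 + d df (standard normal when d0 = ∞).
The prior is estimated by matching the first two moments of log s² to a
scaled F distribution: `e = log s² − ψ(d/2) + log(d/2)`; the excess of
var(e) over ψ′(d/2) is inverted through the trigamma function (Newton
iteration) to give d0, and s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)).  When
var(e) shows no excess spread, d0 = ∞ and s0² is the arithmetic mean of
the sample variances.  This is exactly the procedure of the standard
Bioconductor empirical-Bayes implementation, and the test suite verifies
agreement with it (run through Rscript) to 1e-8 on both the prior and the
per-gene statistics.  `d0_override=0` disables moderation and reduces to
the ordinary pooled t exactly.  A variance floor of 1e-8 guards degenerate
zero-variance rows in synthetic edge cases.

Markers are selected at raw P < 0.05 *and* |log2FC| > 2 (both strict).
Raw rather than FDR-adjusted P is deliberate: at these group sizes no
miRNA survives adjustment, and the score is defined on the unadjusted
criterion; adjusted P-values are still reported for every miRNA.

## miR-score and ROC analysis

The score is the unweighted mean of the selected markers' log2 expression.
Because the markers are down-regulated in malignancy, low score predicts
malignant, and a sample exactly at the cutoff is called malignant —
favouring sensitivity, which is what a rule-out test must protect.

ROC thresholds are the midpoints between consecutive distinct scores plus
±∞, so each achievable operating point appears once and tied scores are
unambiguous.  AUC is the trapezoidal area, equal to the Mann-Whitney
statistic with half-credit for ties (verified against a concordant-pair
enumeration oracle and scikit-learn).  The Youden cutoff maximizes
J = sens + spec − 1; ties are broken toward higher sensitivity, then lower
threshold — deterministic.

Confidence intervals are 95% percentile intervals from 2000 stratified
bootstrap replicates (resampling within class, so no replicate loses a
class).  By default the Youden cutoff is re-estimated in every replicate,
propagating threshold uncertainty into the downstream metrics; a
fixed-cutoff mode exists because the original analysis does not specify
which was used.  Percentile intervals need not bracket the point estimate
in pathological cases; this is logged, not asserted.  Whether the
all-sample evaluation reuses the wild-type cutoff or refits it is equally
unspecified; both modes are provided and refitting is the default.
For the binary mutation marker, AUC = (sens + spec)/2 — the area under a
single-operating-point ROC — and ratios with zero denominators are
reported as undefined (NaN), never as 0.

## RT-PCR cross-validation

Relative expression is 2^−ΔΔCt with arithmetically averaged triplicates
and a calibrator sample anchored at rq = 1.  Platform agreement is
assessed by Passing-Bablok regression with the count platform as the
reference method: the slope is the shifted median of pairwise slopes
(pairs with tied x are undefined and skipped; slopes of exactly −1 are
discarded; the median index is offset by the number of slopes below −1),
the intercept is median(y − b·x), and CIs use the rank-based normal
approximation, with a pair-resampling bootstrap available for very small
n.  The y variable is rq by default; log2(rq) is available and is the
natural scale when the distortion is linear in log2 expression.

## Synthetic cohorts: what they emulate

Counts are Gamma-Poisson (negative binomial, dispersion 0.1 — typical for
digital counting), with log-normal library-size factors (sd 0.3) so
normalization is non-trivial, and an additive non-specific background of
~8 counts so that unexpressed probes resemble a real instrument floor.
100 of the 798 endogenous probes are "expressed", with log2 mean counts
log-uniform over [4.5, 14] — a long-tailed abundance distribution spanning
four decades — so that on the order of 100 miRNAs pass the expression
filter and the top-100 normalization is anchored by many probes, not by
the markers.  The default cohort is 60 nodules (FA 22 wt + 2 mut, FV-PTC
16 wt + 14 mut, NIFTP 3 wt + 3 mut), with one low-RNA-content sample
(counts scaled by 0.05) and one internal-positive-control failure (flag
only), placed in the wild-type FA and FV-PTC cells so the analyzable
comparison is 21 vs 15.

The two planted markers sit at baseline log2 = 10, shifted by −2.5 in
FV-PTC, by an extra −1.0 in any mutation-positive sample; wild-type
NIFTPs stay at FA level while mutated NIFTPs follow the FV-PTC level.
Per-sample biological spread of the true marker level is Gaussian with
sd 0.4 — chosen, together with the baseline model, so the planted
|log2FC| > 2 signal is recoverable by the selection rule in the large
majority of seeds while remaining inside the negative-binomial noise
regime.  Ct tables follow
Ct = intercept − ct_slope · (true log2 expression) + N(0, sd) per
replicate; ct_slope defaults to 0.2 to emulate the strong proportional
distortion between counting and amplification-based platforms, and
ct_slope = 1 with zero noise gives the exact ΔCt identity used in tests.

What passing tests do **not** show about real data: the generator's
within-class variation is homogeneous and Gaussian on the log scale, so
synthetic AUCs (≈0.9-1.0) exceed what heterogeneous clinical material
yields; the two markers' planted shifts are shared across classes, so
*across* histologies their expression is strongly correlated in synthetic
cohorts even though their within-class noise is independent — on real
nodules the between-marker correlation was reported near zero; and the
synthetic PCA spreads variance more evenly than real expression data,
where the leading two components carry on the order of half the variance.

## Problem sizes used in validation

The validation suite runs 50 independent default cohorts for the marker
recovery study; 5000 simulated variances for the prior-recovery check
(d0 = 4, s0² = 1, recovered within ±1 and ±0.15); 200 binormal cohorts
(40 + 40 samples, true AUC 0.8) for bootstrap-CI coverage, required to lie
in [88%, 99%]; exhaustive oracle comparisons for AUC up to n = 30 and for
Passing-Bablok up to n = 15; and a planted proportional distortion of 0.2
recovered at n = 100 pairs.

## Known limitations

Vendor RCC files are not parsed (a flat TSV/CSV is the interface; a
converter is the documented extension point).  No background subtraction
or positive-control linearity QC.  Two-group designs only — no covariates,
paired designs or multi-group contrasts.  No amplification-efficiency
correction in the ΔΔCt step.  DeLong AUC variance and BCa bootstrap are
not implemented (percentile CIs per the 2000-replicate convention).
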