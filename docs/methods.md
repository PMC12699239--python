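# Methods

## The problem

Roughly one in ten testicular Leydig cell tumors behaves malignantly, and no
single histopathologic feature separates these from their benign
counterparts reliably. A practical route to a tissue biomarker is microRNA
RT-qPCR: profile many microRNAs on a small discovery cohort, carry the
strongest candidates into a larger validation cohort, and combine the
validated markers into a voting panel. `mirnapanel` implements that
two-phase workflow as a reusable, tested pipeline, together with a synthetic
cohort generator so every stage can be exercised end to end without access
to raw instrument data.

## Relative quantification (2^-ddCt)

Raw input is one Ct value per well. A well with Ct strictly above the
negativity threshold (default 35 cycles) or that never amplified is
negative; Ct = 35.000 exactly still counts as detected (a literal reading of
"over 35"). Technical replicates are averaged over detected wells only, with
the sample SD (ddof = 1) reported and a QC flag raised above 0.5 cycles;
flagged aggregates are kept — discarding is a curation decision left to the
validation report, not something the arithmetic should do silently.

Within each sample, dCt = target mean Ct − arithmetic mean of the reference
assay mean Cts (for multiple references this equals normalizing by their
geometric-mean expression). ddCt subtracts the mean dCt of the calibrator
group — the benign samples — so relative expression 2^-ddCt has geometric
mean 1 over the calibrators by construction, the package's central
normalization invariant. Undetected targets propagate as missing values,
never imputed at the threshold: imputation would fabricate fold changes,
whereas detection fractions are available to the screen for filtering.
A `global_mean` mode normalizes against the mean of all detected targets of
a sample instead, the usual fallback for array cards whose endogenous
control is unstable; the endogenous control is the default.

## Discovery screen

Each testable assay (≥ 50% detection in at least one group, ≥ 1 value per
group) is tested with a two-sided Mann–Whitney U test — exact permutation
distribution for pooled n ≤ 20 without ties, normal approximation with tie
and continuity corrections otherwise — and summarized by
log2FC = log2(geometric mean malignant / geometric mean benign), which on
the Ct scale is simply the negated group difference of mean ddCt.

Candidates are ranked by a combined score gated by two thresholds,
p < 0.05 and linear fold change ≥ 2 (|log2FC| ≥ 1):

    score = -log10(p) + |log2FC|,  0 for assays failing either gate.

A literal sum of a p-value and a fold change mixes a quantity where smaller
is better with one where larger is better and has no usable ordering; the
implemented score preserves the intended joint significance/effect ranking
on a monotone, dimensionless scale and is gated by exactly the two stated
thresholds. Ties are broken by smaller p, then assay id. No multiple-testing
correction gates the screen by default — screening 768 assays at raw
p < 0.05 is deliberate discovery-phase behavior — but Benjamini–Hochberg
q-values are always computed and reported, and `use_q_values=True` switches
the gate to them.

## Marker validation

Per marker, the empirical ROC curve is computed over all distinct score
thresholds with trapezoid AUC (equal to the tie-adjusted concordance
U/(n1·n2)). Downregulated markers are negated before thresholding so a
higher processed score always means "more malignant"; all reported cutoffs
are mapped back to the original expression scale. The operating cutoff
maximizes Youden's J = sensitivity + specificity − 1 over midpoints between
adjacent distinct observed values (plus guard points beyond the extremes),
so no training sample can sit on the boundary; ties prefer higher
specificity, then the lower cutoff. Sensitivity, specificity, PPV, NPV and
accuracy follow from the confusion counts, with zero-denominator ratios
reported as missing rather than zero.

Association is quantified by univariate logistic regression
(maximum likelihood via statsmodels), reporting the odds ratio per unit of
relative expression with Wald 95% CI exp(slope ± 1.96·SE); a flag switches
to per-log2-unit (per doubling). Complete or quasi-complete separation — a
diverging slope (|slope| > 15) or the fitter's separation signal — is
flagged and the fit marked non-converged; Firth or profile-likelihood
intervals are out of scope.

## The k-of-n voting panel

Each marker votes on each sample: strictly above its cutoff for an up
marker, strictly below for a down marker (midpoint cutoffs make boundary
hits impossible on training data). Missing measurements cast no positive
vote but are counted and reported per sample, which is conservative and
avoids excluding samples. A sample is panel-positive when at least k of the
n markers vote positive. Sweeping k = 1..n, sensitivity is non-increasing
and specificity non-decreasing because the positive set shrinks
monotonically — an invariant asserted on random configurations.

Two AUCs are reported on purpose: the binary-rule AUC of a chosen k, the
trapezoid area of the two-point ROC {(0,0), (1−spec, sens), (1,1)} =
(sens + spec)/2, which is the arithmetic a published single-operating-point
panel AUC corresponds to; and the full ROC AUC over the integer vote count
as an ordinal score. Neither dominates the other in general, so neither is
silently substituted for the other. `best_k` maximizes the binary-rule AUC
with ties resolved toward the stricter (larger) k.

## Unsupervised views

PCA (full SVD, after per-assay z-scoring by default — the heatmap
convention) and agglomerative hierarchical clustering (euclidean or
correlation distance; average, complete or ward linkage; average linkage
default) provide the structure views of the candidate slice. Missing cells
are row-mean imputed first. Dendrograms serialize to Newick, and the
linkage defaults are conventions, not published choices. Stochastic
embeddings (t-SNE, UMAP) are intentionally not implemented: they are visual
methods with no quantitative surface to test.

## Synthetic cohorts

The generator works on the raw Ct scale, where the analysis's assumptions
are native: Gaussian noise in cycles is log2-normal expression noise, and a
planted log2 fold change of f is a ΔCt shift of −f because one PCR cycle is
one doubling. Per sample, a latent reference Ct ~ Normal(20, 0.5) models
input-amount variation; per (sample, assay), a latent
dCt ~ Normal(baseline − group·f, baseline_sd); each replicate adds
Normal(0, replicate_sd). Wells landing above the negativity threshold are
emitted as "Undetermined" when dropout is enabled — deterministic
truncation, the simplest model consistent with the Ct > 35 rule.

Defaults, chosen once as qPCR conventions and exposed as parameters:
baseline (biological) SD 1.5 cycles, replicate (technical) SD 0.15 cycles.
The two-phase preset mirrors the published study design: discovery with 5
benign + 6 malignant samples on a 768-assay single-well card (27 assays
planted up, 23 down, magnitudes evenly spaced 1.2–4.0 log2 units so a
best-candidate ordering exists; baselines spread over 3–13 cycles so a
realistic minority of weak assays sits near the detection limit) and
validation with 18 benign + 17 malignant samples on the six named candidate
markers (planted log2FC ±2) plus an RNU48-like reference, in triplicate.

What the generator does **not** emulate: plate/batch effects, FFPE
degradation gradients, amplification-efficiency differences between assays,
inter-lab variation, or correlated co-regulation between microRNAs. Passing
tests therefore demonstrate that the pipeline's arithmetic and inference
behave as specified under the model the analysis assumes — not that the
biological markers themselves would validate in new tissue.

## Problem sizes and numerical choices

Statistical test fixtures use the study-shaped sizes directly (5/6 and
18/17 per group; 768- and 1000-assay screens), which keep the full suite
and the acceptance script each within a few seconds. With biological SD 1.5
at n = 18/17 the sampling SE of a group log2FC difference is ≈ 0.5, so
fold-change recovery is asserted on each assay's mean estimate across 20
seeded cohorts (observed deviations ≤ 0.21 log2 units); the null screen's
type-I error is checked against 99% binomial bounds at 1000 assays.
Candidate identity at the very top of the discovery ranking is not
statistically identifiable at n = 5/6 when planted magnitudes differ by
0.1 log2 units, so tests assert the stable property instead: every selected
candidate carries a genuinely planted effect in the reported direction.

Degenerate inputs are handled explicitly: an all-tied pooled sample returns
U = n1·n2/2 with p = 1; an uninformative marker yields J = 0 with the
all-negative cutoff; assays with no detected calibrator sample become
all-missing columns with a warning rather than an error; zero-denominator
predictive values are missing, not zero. Floating-point comparisons in the
calibrator-mean invariant use standard double tolerances (the geometric
mean of calibrator expression equals 1 up to rounding).
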