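# Methods

## The analysis problem

Subjects from nuclear families with asthma-ascertained offspring are
assayed on an allergen microarray; each serum yields one reactivity
value per allergen. The analysis asks three questions: (1) do subjects
fall into groups with distinct IgE reactivity *profiles*, and do those
groups differ in asthma and related atopic traits; (2) can a reduced
panel of asthma-relevant allergens sharpen those group differences and
support a classifier of asthma status; (3) do the associations survive
when the family structure of the cohort — siblings and parents are not
independent observations — is modelled explicitly.

## Quantification and the class-score scale

Spot fluorescence is background-subtracted (floored at zero) and
interpolated on a per-slide calibration curve anchored at reference
concentrations 0.35, 1.0, 3.5, 10.0 and 50.0 IU/ml. Interpolation is
piecewise linear in (log₁₀ concentration, log₁₀ signal): immunoassay
response is locally power-law, so log–log segments approximate it well;
the interpolation form between knots is a package convention.
Signals below the lowest knot are below the 0.35 IU/ml detection limit
and report as 0 (class 0); values above the 100 IU/ml assay ceiling
clamp to class 5 with a warning.

The clinical class scale is printed at two-decimal precision
(0.35–0.7, 0.71–3.5, …), which leaves infinitesimal gaps between bins.
The implemented scale closes each gap at its midpoint with half-open
bins — edges 0.35, 0.705, 3.505, 17.505, 50.005 — so the encoder is
total and monotone on [0, 100] and agrees with the printed labels at
printed precision.

## Synthetic cohort generator

The generator emulates the study design, not any particular dataset.
Defaults (all configurable through `CohortSpec`):

| parameter | default | rationale |
|---|---|---|
| families | 283 | study-scale cohort |
| two-parent fraction | 0.562 | ~442 parents across 283 families |
| offspring per family | P(1,2,3) = .55/.38/.07 | ~430 offspring, 1–3 sibs |
| asthma, offspring | 99.5% affected, 0.5% undefined | affected-offspring ascertainment |
| asthma, parents | 12.9% affected / 77.4% not / 9.7% undefined | parent prevalence pattern |
| familial correlation ρ_fam | 0.35 | moderate shared exposure/heritability |
| panel size | 103 | assay panel width |
| signature | 12 allergens, +1.0 SD | planted asthma effect |
| background mean (log₁₀ IU/ml) | −1.5, SD 0.6 across allergens | most cells below detection |
| within-subject noise SD | 1.0 (log₁₀) | heavy right skew of IgE titres |
| below-detection fraction | 0.30 | censoring typical of IgE panels |

Reactivity is built on the log₁₀(IU/ml) scale as background(allergen)
+ family factor + signature shift + noise, exponentiated, and clamped
to [0, 100] IU/ml. The family factor carries ρ_fam of the variance, so
log-profiles of relatives correlate at ≈ ρ_fam. Asthma-affected
subjects are shifted by the signature effect (in units of the noise SD)
on signature allergens only; undefined-diagnosis subjects get half the
shift, since their group mixes true states. Secondary traits
(rhinitis, eczema, conjunctivitis) couple to asthma through a
configurable odds ratio applied symmetrically on the logit scale
(defaults 3.0/1.5/3.0). With these defaults ~87% of class scores are 0
and class 5 is the rarest level (~0.3%), matching the sparsity that
motivates merging class 5 into 4 in the regression coding.

What the generator does **not** emulate: assay-level artifacts (spot
replicates, slide effects), genetic relatedness beyond a single shared
family factor, trait-specific familial correlation, age- or
sex-dependent reactivity, and cross-reactivity structure between
allergens (columns are independent given the family factor). Passing
tests therefore demonstrate that the pipeline recovers planted
structure of this form — not that it would recover every structure
present in real sera.

## Clustering and validity ensemble

Lloyd's k-means with Euclidean distance; initial centroids are k
distinct subjects drawn uniformly (seeded), 25 restarts, best
within-cluster sum of squares kept; the iteration cap defaults to
10,000. An empty cluster is re-seeded at the point farthest from its
assigned centroid and the event is recorded.

Five validity indices score each candidate k ≥ 2 (k = 1 is excluded —
most indices are undefined for a single cluster): Silhouette (higher
better; a singleton cluster's points score 0 by convention), Dunn
(higher), Davies–Bouldin (lower), C-index (lower), and Isolation
(higher) defined as the mean fraction of a point's q = 10 nearest
neighbours sharing its cluster. C-index and Isolation are not uniquely
standardized in the clustering literature; the definitions here are
stated conventions, tested against independent direct-formula
implementations. k is chosen by plurality vote of the per-index
optima; vote ties break by mean rank across indices, then by smaller k.

## Association tests

Pearson χ² without continuity correction (large samples); a warning is
attached when more than 20% of expected counts fall below 5.
Subjects with an undefined diagnosis are excluded *per trait*, so each
trait's table has its own total. Unadjusted p-values are reported (the
filtering threshold is deliberately raw), with a Bonferroni column
alongside for transparency. Family co-segregation uses a permutation
test (default 10,000 seeded permutations) on the mean within-family
fraction of member pairs sharing a cluster; permuting subject→cluster
labels preserves cluster sizes while breaking family structure. The
matched case-control subset pairs each asthmatic parent with the
nearest-age non-asthmatic parent of the same sex, greedily and without
replacement.

## Mann–Whitney filter

Two-sided test per allergen on class scores (a switch allows IU/ml);
exact enumeration when n₁+n₂ ≤ 20 with no ties, otherwise the normal
approximation with tie-corrected variance and continuity correction.
Retention uses raw p < α (default 0.05); Benjamini–Hochberg q-values
are emitted as an extra column but do not affect retention. On
heavily tied class-score data the test is slightly conservative at the
per-column level; across replicate cohorts the retained-count mean
matches the nominal rate, while counts within one cohort co-vary
because all columns share the same asthma split — calibration checks
therefore treat per-cohort counts as the exchangeable replicates.

## NRBF classifier

Two-stage fit, fully deterministic given the seed: hidden-unit centers
by k-means on the training features; width of each unit = distance to
its nearest other center (floored at 10⁻⁶); Gaussian activations
normalized to sum to one (so the hidden layer is a partition of unity
and the network interpolates between local experts); output weights by
least squares on one-hot labels, with a ridge fallback (λ = 10⁻⁶) if
the system is singular. The hidden-unit count h is selected from 2–10
by accuracy on the 10% test split. Stratified splitting keys each
subject by its relative rank within its class so a global cut at the
60/10/30 boundaries keeps both classes near their overall proportions
in every split. Pseudo-probabilities are the softmax of the output
scores; exact ties predict class 0. The protocol repeats 10 times on
fresh networks and reports means and SDs of holdout sensitivity,
specificity and accuracy; the ROC (combined train+test) uses a
threshold sweep whose trapezoid AUC equals U/(n₁n₂) exactly.

## GEE

Marginal binary regression with exchangeable working correlation over
families and robust sandwich covariance, fitted by statsmodels
(estimating-equation tolerance 10⁻⁸, max 100 iterations). The link
defaults to logit so coefficients exponentiate to odds ratios; probit
is available behind `GEEConfig.link` (a latent-threshold data-generating
process with unit total variance yields exact marginal probit
coefficients, which is how parameter recovery is validated). If the
exchangeable iteration diverges, the model refits under an independence
working correlation — still a consistent GEE whose sandwich errors
remain family-robust. |β| > 15 triggers a separation warning, and
terms with non-finite robust SEs report NaN inference rather than
failing the whole fit.

Class scores enter as 4-level factors (5 merged into 4; reference 0;
constant indicator columns dropped). The univariate screen tests each
allergen's factor with a global Wald χ² on the robust covariance;
forward selection starts from the covariates-only model (age, sex,
age×sex, raw age — centering is not used), adds the candidate with the
smallest global Wald p while p < 0.05, and screens candidates whose raw
scores have Cramér's V > 0.9 with an already-selected allergen.
Known limitation: with very sparse upper levels (a handful of
subjects at class ≥ 4 concentrated in few families) the 4-df robust
Wald test can be anti-conservative, so the univariate screen may
over-retain on sparse panels; the class-5 merge mitigates but does not
eliminate this.

## Pipeline and problem sizes

`run_pipeline` chains simulate → quantify → cluster (all allergens) →
associate → filter → re-cluster (filtered panel) → associate → NRBF →
GEE screen/forward-selection, writing TSV/JSON artifacts plus a
manifest (inputs, seeds, stage timings). All artifacts regenerate
bit-identically under a fixed master seed; the manifest itself embeds
wall-clock timings and is not byte-stable. The before/after-filter
asthma association is compared on the same defined-diagnosis subjects.
The pipeline's GEE screen runs on the filtered panel; the full
103-allergen screen is available in `analysis/07_gee_analysis.py` and
the `gee` CLI subcommand. Test and demonstration runs use
study-scale cohorts (~870 subjects) for single analyses and smaller
cohorts (40–150 families) for replicate-based calibration checks, with
replicate counts chosen so Monte-Carlo error is small relative to the
tolerance being checked (e.g. 200 replicates for robust-CI coverage).

## Open design choices taken

- Interpolation form of the calibration curve (log–log linear) and the
  midpoint closing of the printed class-bin gaps.
- Isolation/C-index formulas (stated conventions, see above).
- k-selection aggregation rule (plurality of indices with rank/small-k
  tie-breaks).
- Logit default for the regression link despite a probit variant being
  equally defensible; both are provided.
- The family co-segregation statistic and its permutation null.
- Trait-coupling odds ratios within families are user-set: the joint
  within-family distribution of traits is not modelled beyond the
  shared reactivity factor.
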