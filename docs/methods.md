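# Methods

This note documents the models, conventions and numerical choices behind
`rankmarkers`, and what the synthetic-data generators do and do not
emulate.

## Discovery: dual rank-tier selection

Given two cohorts quantified on incompatible within-sample-normalized
scales, per-gene arithmetic means are computed on the raw linear scale
(zeros included, no expression floor — unexpressed genes simply rank
last), genes are sorted descending within each cohort, and the panel is
the intersection of the tumor top tier with the normal bottom tier.

Conventions, each chosen where the procedure is otherwise underdetermined:

- **Tier boundary = ceiling.** ⌈G·f⌉ is the only rounding that makes a
  5% cut of 18,734 genes contain exactly 937 genes (floor gives 936), and
  a 50% cut contain 9,367.
- **Ties broken lexicographically by gene id**, so ranks are a
  deterministic permutation of 1..G on every platform.
- **Identifier harmonization**: strip surrounding whitespace, strip one
  trailing `.<digits>` version suffix, upper-case. Annotation releases
  differ mainly in case and Ensembl-style versioning; anything beyond
  that (alias resolution, retired symbols) is out of scope and the rule
  is deliberately explicit rather than clever. Post-normalization
  collisions within one cohort are an error, not a silent merge.

The justifying property, tested as an invariant, is scale invariance:
multiplying all values of one cohort by any positive constant leaves its
rank table — hence the panel — unchanged.

## Housekeeping normalization

Digital-count assays carry a per-sample technical scale ("lane") factor.
The per-sample correction is

  factor(s) = mean_t( geomean_hk(t) ) / geomean_hk(s),

i.e. every sample is scaled so its housekeeping geometric mean equals the
cohort-average housekeeping geometric mean. The geometric (not
arithmetic) mean is the standard digital-count convention and makes the
procedure exactly idempotent; the invariant "post-normalization
housekeeping geometric means equal across samples to 1e-9 relative
tolerance" is asserted on simulated runs. Zero housekeeping counts are an
error (the geometric mean would collapse); the generator keeps
housekeeping expectations high enough (~1500 counts) that this cannot
occur in simulation.

## Wilcoxon screen

Per gene, a two-sided Wilcoxon rank-sum (Mann–Whitney) test between the
two cohorts: the exact null distribution when the smaller cohort has ≤ 10
samples and the pooled values are tie-free, otherwise the normal
approximation with tie correction and continuity correction. When the tie
correction removes all rank variance (every pooled value equal) the data
carry no evidence and p = 1 is returned directly. Star bands use raw
p-values with cut-points 0.05 / 0.01 / 0.001; no multiple-testing
correction is applied to the bands (a Benjamini–Hochberg FDR column is
emitted alongside for the reader). Tests verify the implementation
against an exhaustive enumeration over all label assignments for total
n ≤ 12, to 1e-12.

## PCA and clustering

Values are transformed ln(x + 1) — the pseudocount is needed because
normalized counts can be 0 — then each gene row is centered and scaled to
unit variance (sample sd, ddof = 1). Zero-variance rows cannot be scaled
and are dropped with a warning. The SVD of the standardized genes ×
samples matrix gives sample scores (right singular vectors × singular
values) and explained-variance percentages (squared singular values as a
share of their total; they sum to 100 when all components are kept, and
the reconstruction loadings · scoresᵀ reproduces the input to 1e-8).

Per-cohort 95% concentration ellipses are fitted as 2-D Gaussian
ellipses on the (PC1, PC2) scores at the chi-square(2) 0.95 quantile; a
point is "inside" when its squared Mahalanobis distance is within that
quantile. Near-singular group covariances have their eigenvalues floored
at 1e-12 × the largest, so a degenerate point-cluster yields a point-like
ellipse rather than a pseudo-inverse artifact that contains everything.

Heatmap orderings cluster both axes of the same standardized matrix with
Chebyshev (maximum) distance and complete linkage; leaf orders follow the
scipy dendrogram convention.

## Threshold accuracy

threshold = fold × max(control values), fold = 5 by default. Strict `>`
decides true positives and `≤` true negatives: "exceeding" is read as
strict, so a value exactly at the threshold counts negative (the choice
is unobservable with continuous values and fold ≠ 1, but it is documented
and unit-tested). With fold > 1 and a positive control maximum the
threshold exceeds every control value, so specificity is identically
100% — the classifier's single operating point is characterized by
sensitivity alone. All-zero controls give the degenerate threshold 0,
flagged in the report; a control at exactly 0 still counts negative.
Sensitivity tiers round half-up to the nearest 5%, which is the
convention under which 40/42 = 95.24% and 38/42 = 90.48% print as "95%"
and "90%".

## Pan-cancer interval discrimination

A (type, gene) expression interval is the empirical
[quantile(q), quantile(1−q)] with q = `trim_quantile`; q = 0 (the
default) gives the full min–max range. Quantiles interpolate linearly
between order statistics. "Range" is read as min–max because the source
analysis reports ranges while displaying box plots; the trim parameter
exposes a whisker-like alternative without asserting which was used.
Intervals are closed and a shared endpoint counts as overlap — the
conservative direction, yielding fewer discrimination claims. A panel's
combined coverage is the union of per-gene non-overlap verdicts; the
residual is the complement among non-target types. Increasing the trim
only shrinks intervals, so it can only add non-overlap verdicts (tested).

## Synthetic data: what it emulates, and what it does not

- **Discovery cohorts.** Background gene means are log-normal
  (exp N(μ=2.0, σ=1.5)) — heavy-tailed and strictly positive so ranks are
  well defined — with per-cell multiplicative log-normal noise
  (σ = 0.25). Defaults use the reference design: 266 tumor / 97 normal
  samples and 41 planted genes. Planted genes get tumor means 20–80×
  above the background maximum and normal means 20–100× below the
  background 5th percentile; with these margins the empirical mean ranks
  cannot leave the required tiers, so planted-truth recovery is a
  construction guarantee, not a statistical hope. The two cohorts carry
  deliberately mismatched id spellings (dot-versions vs lower case) so
  the harmonization step is exercised. Not emulated: gene–gene
  correlation, library-composition effects, batch structure — recovery on
  this generator shows the selection logic is correct, not that real
  TCGA/GTEx data would yield any particular panel.
- **Digital-count run.** Counts are Poisson around scaled log-normal
  means: housekeeping expectations are cohort-independent, panel genes
  are elevated `tumor_over_expression_fold`-fold in tumor samples
  (default 20, chosen once near the log-midpoint of the qualitative
  3–300× over-expression range), and every gene of a sample — including
  housekeeping — is multiplied by a log-normal lane factor
  (σ = 0.3), which is exactly the nuisance normalization must remove.
  With `include_outlier` one tumor sample draws its panel genes from the
  normal-level distribution while keeping its tumor label, reproducing
  the low-expressing-outlier phenomenology (it falls outside the tumor
  95% PCA ellipse in ≥ 95 of 100 seeds). Poisson is only modestly
  over-dispersed; FFPE degradation and probe chemistry are not modelled.
- **Pan-cancer matrix.** Designated (type, gene) values are drawn
  uniformly inside their target interval — so the empirical range is
  contained in the target and designed disjointness is guaranteed — and
  everything else from a shared log-normal background. Type names fill
  from the 33 TCGA study abbreviations. The default 33-type design plants
  three discriminator genes separating the target type from 25, 25 and
  29 other types, jointly covering all but two (UCEC, UCS), mirroring the
  reference discrimination structure.

All generators draw from a single `numpy.random.default_rng(seed)`; a
fixed config and seed give bit-identical matrices.

## Problem sizes

Tests run the full digital-count design (47 genes × 45 samples), discovery
at a few hundred genes, and Monte-Carlo loops of 100 seeds; the acceptance
script additionally runs discovery at the full 18,734-gene universe with
266 + 97 samples and a 33-type × 333-samples-per-type pan-cancer matrix.
These sizes keep every computation exact (no subsampling of the stated
designs) while completing in seconds.

## Known limitations

- Identifier harmonization does not resolve gene aliases or cross-release
  symbol renames; it only canonicalizes case and version suffixes.
- The exact normalization configuration of the proprietary vendor
  software behind housekeeping scaling is not published; geometric-mean
  scaling is the documented, testable convention adopted here.
- The concentration ellipse assumes 2-D normality of group scores; with
  very small groups (3 controls) it is a rough summary.
- The pipeline reports a single threshold operating point by design; it
  does not compute ROC curves or cross-validated accuracy.
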