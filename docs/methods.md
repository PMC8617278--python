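# Methods

This note documents the models, estimators and numerical choices behind
`scsimeval`, and what its synthetic tests do and do not demonstrate about
real data.

## Evaluation model

The framework treats simulator fidelity as a distribution-matching problem.
Nothing is matched gene-by-gene or cell-by-cell: simulated matrices
routinely carry uninformative gene names with no correspondence to real
genes, so all comparisons are made between *distributions of summary
properties*. A real dataset is ideally split 50/50 (stratified by cell type)
into a training half that feeds the simulator and a testing half that serves
as the reference, so that a simulator which memorises its input gains
nothing; `split_train_test` implements this with the extra cell of an odd
group going to the testing half (the reference should not be the smaller
side).

### The 13 data properties

Count-scale properties are computed from raw counts (library size, TMM
factor, effective library size, fraction of zeros per cell/gene); expression
-scale properties from log2-CPM with pseudocount 1 (mean, variance,
z-scaled variance, Spearman correlations between cells and between genes);
three bivariate point sets capture higher-order structure (mean–variance,
mean–fraction zero per gene, library size–fraction zero per cell). TMM and
effective library size require unnormalised counts; when the simulator
emits normalised values they are recorded as unavailable and their scores
stay blank rather than zero.

The TMM factor follows the published weighted trimmed-mean-of-M-values
algorithm: the reference cell is the one whose 0.75-quantile count
proportion is closest to the mean across cells; per cell, log2 ratio (M) and
mean log2 abundance (A) values over genes positive in both the cell and the
reference are double-trimmed (middle 40% of M, middle 90% of A, rank-based
with average ranks) and combined by inverse-variance weights from the
binomial delta method; factors are rescaled to geometric mean 1. On count
data M and A contain many exact ties, and which side of a trim boundary a
tied block lands on depends on last-bit behaviour of `log2`; factors can
therefore differ by a few percent between this implementation and others on
tie-heavy instances while agreeing to 1e-9 on tie-free ones.

Spearman correlation distributions subsample cells/genes to a seeded cap
(default 500) before forming all pairs, keeping the pair count at most
~125k; ties get average ranks; constant features are dropped with a logged
count.

### Kernel-density two-sample statistic

The similarity measure per property is the integrated squared error
T = ∫(f̂₁−f̂₂)² between Gaussian KDEs, evaluated exactly through the identity
∫φ_{H₁}(x−a)φ_{H₂}(x−b)dx = φ_{H₁+H₂}(a−b). Bandwidths are normal-scale
plug-ins: h = σ̂(4/3n)^{1/5} in one dimension and H = n^{−1/3}Σ̂ in two; the
covariance bandwidth absorbs axis scales, so bivariate properties are not
pre-standardised (the statistic is affine-consistent). The bandwidth
selector is pluggable — any h/H can be passed explicitly. Only the
discrepancy magnitude is used; no null distribution or p-value is attached.

Numerics: both double sums are evaluated in blocked form (≤2·10⁶ pairwise
differences per block) to bound memory; the result is clamped at 0 against
negative round-off; sides larger than the cap (default 5000) are subsampled
with a *same-seeded generator per side*, so identical inputs keep identical
subsets — this preserves T(X,X)=0 and exact symmetry under argument swap.

Raw statistics only become comparable scores after the collection-wide
transform: x ↦ 1 − (|x|−min|x|)/(max|x|−min|x|), with min/max taken over all
methods and datasets in the run being aggregated. Scores are therefore
*relative to the collection*: re-aggregating a different set of methods
rescales them, which is why `aggregate_scores` always recomputes the
transform over the pooled table.

### Companion measures

Six alternative measures validate the kernel statistic. The silhouette here
follows the benchmarking convention, not the clustering one: for a simulated
point, a(i) is its mean distance to the real points and b(i) to the other
simulated points, s(i) = (b−a)/max(a,b), averaged over simulated points
(configurable). The k-NN rejection fraction runs a chi-square
goodness-of-fit of each pooled point's k=5 neighbour origins against the
pooled composition and reports the fraction rejected at 5%. K-S distance
and the area between eCDFs (computed as the exact step-function integral
over the range-rescaled pooled support) cover univariate properties, as does
the Wald–Wolfowitz runs z (pooled stable sort, real-side values first at
ties — deterministic).

Mapping to [0,1]: nn-rejection and eCDF area are `1 − raw`; silhouette and
runs use the collection min–max transform; K-S uses a min–max on the
*signed* log distance (log D is monotone in D, so the smallest distance maps
to 1; D = 0 is floored at machine epsilon first). Applying the
absolute-value form to log D would invert the ranking — the most similar
pair has the most negative log — so the signed form is used deliberately.

### Biological signal

Six detector categories run on log2-CPM between the two largest cell
groups (three or more groups: the two largest, deterministic tie-break by
label). Thresholds are BH-adjusted p < 0.1 for the five test-based
categories, combined conjunctively with |log2FC| > 1 for the two DE
detectors; "expressed" means log2 expression > 1 for the DP contingency
test (2×2 chi-square, no continuity correction, p = 1 when a gene is
expressed in none or all cells of both groups); bimodality index
BI = |m₁−m₂|/(s·√(p(1−p))) > 0.03 for BD, with s the pooled within-group
standard deviation and p the proportion of cells in the larger group. Note
the index *divides* by √(p(1−p)) as used here, where part of the
bimodality-index literature multiplies — users comparing cut-offs across
tools should check which form is in play.

The moderated DE detector shrinks gene-wise pooled variances toward a
scaled-inverse-chi-square prior fitted by method of moments on log
variances (digamma/trigamma matching, Newton inversion of the trigamma),
then forms t-statistics on d₀+d degrees of freedom. The second DE criterion
is a Wilcoxon rank-sum test — a nonparametric detector standing where a
zero-inflation-aware external tool would otherwise sit, preserving the
two-detector concordance design without wrapping external software. DD uses
the two-sample K-S test with asymptotic Kolmogorov p-values (accurate at
the ≥100 cells/group sizes the framework targets).

Agreement between simulated and real proportions is
`1 − SMAPE/2 ∈ [0, 1]`, pairs with both proportions zero contributing zero
error. With a single dataset the score reduces to the one-pair formula;
across datasets it is the mean over pairs.

### Aggregation

Per-group scores combine into a dataset score by Σxᵢwᵢ with cell-type
proportions of the *real* half as weights (configurable); groups whose
property was unavailable are dropped and the remaining weights renormalised.
Dataset scores summarise per method by the median, recording how many
datasets contributed; failures stay excluded. Within each criterion methods
are ranked descending (average ranks on ties), ordered overall by mean rank,
and binned into quartile tiers (tier 1 best; bin count configurable — with
very few methods the extreme quartile bins are inevitably occupied).
`fit_cell_number_trend` provides the closed-form least-squares line of score
on cells/1000 used for cell-number trend analysis.

## Synthetic fixtures

The generator emulates a two-group scRNA-seq dataset and its simulated
companion. Counts are hierarchical gamma-Poisson: gene means
λ_g ~ Gamma(0.6, rate 0.3) (heavy-tailed, mean 2 counts — typical of
droplet-style data), cell size factors LogNormal(0, 0.25), NB dispersion
0.3, optional uniform dropout (independent of expression, so expectations
stay analytic; expression-dependent dropout is a labelled extension knob,
off by default). Signal genes are planted in disjoint leading blocks for
group 2: DE genes shift means by ±log2FC 2 (alternating sign), DV genes
multiply dispersion by 4, DP genes switch expressing-cell fractions
0.9 → 0.3, BD genes get a sub-threshold mean gap of 0.8. The simulated
companion redraws *everything* from the (optionally perturbed) law with a
fresh seed, so a zero perturbation yields an exchangeable replicate — the
perfect simulator. Ground truth proportions are returned by
`expected_signal_proportions`.

What the fixtures do not emulate: batch effects, sample-to-sample
heterogeneity within a cell type, gene–gene correlation structure beyond
what normalisation induces, and expression-dependent dropout (by default).
Tests passing on fixtures therefore certify the *measurement machinery* —
that degradations of known direction and size are detected and ordered —
not that any particular real simulator is good.

## Detector behaviour worth knowing

* **Bartlett under non-normality.** Bartlett's statistic is calibrated
  against normal data; its size inflates with kurtosis and the inflation
  grows with sample size. log2-CPM of overdispersed counts is intrinsically
  heavy-tailed, so at 200 cells/group the DV detector flags 10–35% of
  *null* genes at BH < 0.1 (0% on normal data — the implementation is
  exact). Planted DV proportions are consequently over-estimated in
  absolute terms even though planted genes are strongly enriched; DV
  comparisons between simulated and real data remain meaningful because
  both sides incur the same inflation.
* **k-NN rejection discreteness.** With k = 5 the only neighbour
  composition with chi-square p < 0.05 is unanimity, so the test's true
  null level is P(unanimous) ≈ 0.06, slightly above nominal; the measure is
  used comparatively, not as a calibrated test.
* **SMAPE at near-zero proportions.** When one side detects no signal and
  the other a tiny amount, SMAPE saturates at its maximum; profiles of
  datasets with no real signal are therefore all-or-nothing and are best
  interpreted jointly with the property scores.

## Problem sizes used by tests

Deep checks run at 2000 genes × 500 cells with 10 generator seeds
(degradation ordering, end-to-end ranking) and 2000 × 400 for
planted-signal recovery; unit tests use a few hundred genes. The KDE
quadrature oracles integrate explicit mixture densities on 20001-point
(1-D) and 601² (2-D) grids, which bounds their truncation error well below
the 1e-8 / 1e-6 comparison thresholds.
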