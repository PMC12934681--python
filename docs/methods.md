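# Methods

## Data model

The unit of analysis is a flat cell table: one row per segmented cell
with `cell_id`, `sample_id`, `fov_id`, centroid `x_um`/`y_um` (microns,
per-FOV local frame by default), a categorical `cell_type`, and
optionally `total_counts` and a `niche` label. FOVs are square tiles
(default side 500 µm, the standard imaging tile size); an optional
`fov_id → (x0, y0)` offset table lifts local frames into a global
per-sample frame. Counts live in a companion cell × gene matrix
(MatrixMarket or dense TSV) whose rows are a bijection onto the table.

QC removes cells with *fewer than* `min_counts` (default 50) total
transcripts — strictly fewer, so a cell at exactly the threshold is
kept. The filter is idempotent and reports
`n_input = n_removed + n_kept` exactly.

## Contact graph

Two cells are in contact when their centroid distance is ≤ `radius_um`
(default 40 µm; the boundary is inclusive so results are bit-exact and
testable) and they share the scope unit — the same FOV (`per_fov`,
default) or the same sample (`per_sample`, requiring a global frame).
Construction uses one KD-tree per scope unit but is defined to equal
all-pairs thresholding, which the tests enforce on random fixtures up to
500 cells. Ordered pair counts sum, over index-type cells, their
neighbor-type contacts; a homotypic edge therefore contributes 2 (both
endpoints are index cells). Radius is a first-class parameter because
practice varies around the 40 µm default.

## Co-localization permutation test

For an ordered pair (A, B), the cells labelled A are the *index set* and
are held fixed — positions and labels. The statistic is the number of
B-labelled contacts of the index set. The null shuffles the labels of
all non-index cells uniformly; with FOV stratification (default) each
FOV's non-index label multiset is preserved, which keeps local density
and composition intact and is the appropriate null when FOVs differ
systematically. From `n_permutations` (default 1000, minimum 100)
shuffles we take the sample mean and the n−1 standard deviation of the
null counts, and report

* `z = (observed − mean) / sd`;
* a two-sided p-value, by default from the standard-normal tail of |z|
  (counts at these densities are sums of many weak indicators, so the
  normal approximation is accurate); an `empirical` mode
  `min(1, 2·min(p_lo, p_hi))` with the add-one estimator
  `(1 + #{null ≥ obs}) / (P + 1)` is provided for sparse settings;
* Benjamini–Hochberg q-values across all reported pairs (method
  configurable; BH is the field default);
* `log(observed / expected)` enrichment.

Both orders (A, B) and (B, A) are reported: the observed counts are
equal but the nulls differ (different index sets), so both are
informative.

**Degenerate nulls.** If the null sd is 0 the z-score is undefined; the
pair is reported with `p = 1`, `z = NaN` and a `degenerate` flag rather
than an infinite z. This always happens for homotypic pairs (A, A): the
entire type is the index set, no A labels remain among the shuffled
cells, and the statistic is constant. That is inherent to a null that
shuffles only non-index labels — the method tests cross-type proximity;
homotypic clustering needs a positional null, which is out of scope.

**Closed form.** Under the non-stratified shuffle, linearity of
expectation gives `E = M · n_B / N`, with M the ordered contacts from
index cells to non-index cells, n_B the non-index cells labelled B and N
all non-index cells. The implementation is checked against this closed
form, and on small fixtures against exhaustive enumeration of all label
permutations.

**Implementation.** Per index type, each cell's multiplicity of contacts
from the index set is precomputed; a null draw is then a weighted
bincount over permuted labels, and permutations are batched as argsorts
of iid uniforms (one matrix per FOV stratum). This keeps 1000
permutations × all pairs on an 800-cell sample below 0.1 s.

**Per-FOV hotspot maps** repeat the test inside each FOV with
FOV-internal shuffles and report
`log((obs + c) / (exp + c))`, pseudocount `c = 0.5` keeping the score
finite when either side is 0 (raw observed and expected are also
emitted). FOVs lacking index or candidate neighbor cells yield a
flagged null row.

## Niche assignment

Each cell is featurized by the cell-type composition of its k = 20
nearest neighbors (self excluded, within-FOV, stable tie-break at the
k-th distance; k capped at n−1 in small FOVs). Composition vectors are
clustered with k-means (fixed seed, 10 restarts), and clusters are
relabelled by descending size so ids are stable up to that convention.
This is the standard published k-NN-composition approach; the
proprietary vendor niche routine it emulates is undocumented, so only
structural recovery on synthetic truth — not label-level equivalence —
can be claimed. Region restrictions (e.g. nodule-interior cells drawn
from histology) enter as user-supplied masks on the composition tables;
the package does not segment regions from expression.

## Signatures

Module scores follow the bin-matched control scheme: genes are ranked by
dataset-average expression into 24 equal-size bins; each set gene draws
100 control genes with replacement from its bin; the score is
mean(set) − mean(pooled controls), computed on library-size-normalized,
log1p-transformed data (`normalize_log1p`; any pre-normalized matrix is
accepted — variance-stabilizing residual normalization is deliberately
not reimplemented). The score is exactly 0 on a constant matrix and
invariant to adding a constant to every entry. Gene sets are user
input; no gene-set database retrieval is bundled.

Transcript-source attribution is the exact decomposition
`fraction_t = Σ counts(gene, cells of type t in region) / Σ counts(gene, region)`,
flagged all-zero when the gene has no regional counts.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions used throughout the test suite.

* **Baseline**: per FOV, `N ~ Poisson(base_density)` cells placed
  uniformly (CSR), types iid from `type_freqs`. Defaults: 1 sample,
  4 FOVs of 500 µm, 200 cells/FOV — the low end of a real tile; tests
  use 200–500/FOV.
* **Attraction** (Thomas-style shared parents): per FOV,
  `Poisson(parent_intensity = 10)` parents placed uniformly; a
  `strength = 0.8` fraction of each partner type's cells is re-placed at
  a uniformly chosen parent plus isotropic Gaussian noise
  (`offspring_sigma_um = 15`), clipped to the FOV. Shared parents make
  the direction of the induced A–B excess analytically predictable,
  unlike pairwise Gibbs interactions. A relation may be restricted to a
  subset of FOVs (`fov_ids`) to plant localized hotspots.
* **Repulsion**: a strength-fraction of type-B cells is re-drawn until
  it clears `exclusion_radius_um = 40` from every type-A cell (retry cap
  100 per cell; exceeding it raises an error naming the pair). The
  resampling is one-sided (B avoids A) — the induced A–B contact deficit
  is symmetric, and one-sided placement keeps the A pattern exactly CSR.
* **Mosaics**: non-overlapping rectangles (fractions of the FOV side)
  with their own type frequencies and densities; every cell carries
  exactly one ground-truth region label.
* **Counts**: per gene and type, negative-binomial
  (gamma–Poisson, mean µ, size θ = 1); baseline means lognormal
  (median 0.2/gene over a 1,000-gene panel, matching the few-hundred
  counts/cell of real panels), with disjoint 10-gene marker blocks per
  type at fold-change 10. Genes are independent given the type — enough
  first-order structure for scoring and attribution, with no
  gene–gene correlation.
* Edge effects are uncontrolled (no toroidal wrap), as in real FOVs.
  All three generators are deterministic under the spec seed.

**What the synthetic data does not emulate**: segmentation error and
transcript misassignment between neighboring cells, spatial expression
gradients within a type, batch effects across samples, cell-size
variation, and gene–gene covariance. Passing recovery tests therefore
demonstrates correctness of the statistics under the declared point
process, not robustness to those real-data artifacts.

## Calibration and recovery conditions

The test suite checks, at fixed seeds:

* type-I error on 50 neutral CSR datasets (4 FOVs, density 200, 4 equal
  types): the fraction of cross-type p < 0.05 must land in [0.02, 0.08];
* power and direction on planted attraction/repulsion (strength 0.8,
  σ = 15 µm, exclusion 40 µm, density 300): z of the planted pair has
  the planted sign with q < 0.05 in ≥ 90% of 20 seeds;
* hotspot localization with attraction injected in half of 8 FOVs
  (one-sided Wilcoxon on per-seed injected-minus-neutral mean
  log-enrichment, p < 0.01 over 20 seeds);
* niche recovery on a two-regime mosaic. The planted regimes are fully
  segregated (left/right half-FOV blocks, 0.9-dominant disjoint types,
  density 500/FOV): mean ARI ≥ 0.9 over 10 seeds, and chance-level ARI
  when both blocks share frequencies. The k-NN featurization mixes
  regimes in a boundary band of width ≈ √(k/(πλ)) (≈ 56 µm at k = 20,
  λ = 500/FOV), so ARI against the geometric truth approaches but never
  reaches 1; weakly contrasted or sparse mosaics recover correspondingly
  less.

## Numerical choices

* Null sd uses the n−1 estimator (unbiased, fixed for reproducibility).
* The graph boundary (distance = radius) is inclusive.
* Stable argsort breaks k-NN distance ties by cell order.
* FOV strata with fewer than two non-index cells are left unchanged
  during shuffles (logged no-op).
* A single pipeline seed derives all stage seeds via seed sequences
  (all below 2³¹); per-index-type streams make the single-pair test
  reproduce the corresponding row of the all-pairs table.
* Pipeline outputs carry no timestamps, so identical configs reproduce
  byte-identical files (hash-recorded in the manifest).

## Limitations

* Homotypic pairs are untestable under the label-shuffle null (reported
  degenerate, see above).
* The normal-from-z p-value is anti-conservative when expected counts
  are very small; use `p_mode="empirical"` there.
* Per-sample graphs require FOV offsets; the package does not infer
  tile layout.
* No ligand–receptor inference, pseudotime, spatial gene-module
  discovery, or cross-sample meta-analysis of z-scores.
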