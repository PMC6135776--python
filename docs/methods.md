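# Methods

`phenonet` implements a cell-network approach to tissue phenotyping of
histology sections and the prognostic statistics built on top of it.
The input is not pixels but the *cell map* a detection/classification
model produces from a whole-slide image: one record per cell with its
centroid in µm (origin top-left, y downward) and one of four classes —
malignant epithelial (M), inflammatory (I), spindle-shaped (S,
fibroblasts and smooth muscle) and necrotic debris (N) — plus a
categorical tissue mask over nine appearance classes.  Because no
patient data ships with the package, a synthetic-data module generates
both inputs with known structure; every empirical number the tests and
the acceptance script report is computed on those simulations.

## Tile networks and connection-frequency vectors

A slide is cut into non-overlapping 200 × 200 µm tiles (half-open
intervals, so a cell on a shared boundary belongs to exactly one tile;
200 µm is the scale of effective intercellular communication).  Within
each tile the cells are joined by their Delaunay triangulation; edges
never cross tile borders.  With four cell classes there are ten
unordered type pairs, indexed canonically as
(1,1),(2,1),(2,2),(3,1),(3,2),(3,3),(4,1),(4,2),(4,3),(4,4) over
M=1, I=2, S=3, N=4, and each tile is summarised by the vector
h ∈ R¹⁰ of edge-type proportions, which lies on the simplex whenever
the tile has at least one edge.

Degenerate inputs follow the natural one-dimensional limits: two cells
give a single edge and three or more collinear cells give the
consecutive-neighbour path along their line.  Exactly coincident
coordinates are merged to one vertex (first record's type, with a
warning) because a triangulation needs distinct sites.  Cocircular
ties are left to the geometry backend's deterministic handling; the
test fixtures use generic (random continuous) positions where such
ties have probability zero.  Tiles with fewer than `min_cells = 5`
cells are marked unphenotyped and excluded from clustering — tiny
networks produce unstable proportion vectors.  No edge-length cutoff
is applied within tiles.

## Phenotype discovery

All phenotyped tiles of a cohort are pooled and clustered by k-medoids
under the chi-squared histogram distance

    d(h, m) = Σ_k (h_k − m_k)² / (h_k + m_k),

with zero-sum components contributing nothing; on the simplex d is
symmetric, vanishes only at equality and is bounded by 2.  The search
is partition-around-medoids style: from a uniformly random medoid
subset, the single best strictly improving (medoid, non-medoid) swap
is applied until none exists, so the cost is non-increasing and the
result is a local optimum.  Swap deltas are evaluated with a
FastPAM-style decomposition Δ(i, j) = A(j) + B(i, j) — A the cost
change of adding candidate j, B the correction for points losing their
nearest medoid i — which makes one iteration O(n²) element operations
independent of k.  The protocol runs 100 random restarts and keeps the
minimum-cost replicate; an `init="exhaustive"` mode starts one
replicate from every k-subset, which provably attains the global
optimum and is used in the oracle tests.  Assignment is
nearest-medoid, ties broken by the lowest medoid index.

The number of phenotypes is chosen by scanning k (default 2..10) and
keeping the **largest** k that is admissible under two criteria: the
minimum pairwise chi-squared distance between medoids must be ≥ 0.2,
and the maximum absolute Spearman correlation over all pairs of
per-case phenotype-ratio features must be ≤ 0.8.  A closer medoid pair
or a more correlated feature pair indicates a redundant split.  The
per-case ratio features for this criterion use tile counts; the
denominator is the case's tissue area in tile units when supplied,
otherwise the phenotyped-tile count.  The maskless denominator closes
the composition (ratios sum to 1), which at k = 2 makes the two
features perfectly anticorrelated — supplying tissue areas avoids
this, and the correlation maximum treats NaN (constant columns) as no
evidence of redundancy.

Phenotype names (`smooth_muscle`, `inflammation`,
`tumor_stroma_interface`, `tumor`, `stroma`, `necrosis`) come from a
dominant-pair heuristic on each medoid — necrotic edge mass ≥ 0.2 →
necrosis; M–S mass ≥ 0.3 (or ≥ 0.15 and exceeding both M–M and S–S) →
tumor-stroma interface; otherwise the dominant type, with nearly pure
S–S spectra (≥ 0.7) called smooth muscle and mixed spindle spectra
stroma.  Names are cosmetic and never affect any number; a
user-supplied mapping overrides the heuristic.

## Per-case features

With the tissue mask, tissue area is the pixel area of every class
except normal mucosa, fat and non-tissue background.  Each CF
phenotype's ratio is the tissue-pixel area inside its tiles over the
case's tissue area; without a mask, tile counts over the
phenotyped-tile count are used (and then sum to 1).  The AP
smooth-muscle and inflammation ratios are class areas over tissue
area; the stroma–tumor and necrosis–tumor ratios are
stroma/(stroma+tumor) and necrosis/(necrosis+tumor) on mask areas.
Ratios with a zero denominator are reported missing, never zero.

Spatial coexistence of inflammatory and malignant cells is measured by
the Morisita–Horn overlap of their counts in 200 µm quadrats aligned
with the tile grid:

    MH = 2 Σ x_q y_q / ((Σx_q²/X² + Σy_q²/Y²) · X · Y),

in [0, 1], symmetric in the two populations and invariant to uniform
count scaling; it is missing when either population is absent.  The
choice of the Morisita–Horn form and of tile-sized quadrats is a
design decision of this package — the colocalization literature this
index comes from uses several variants, and this is the standard one
for two-population spatial overlap.  Results depending on it should be
read with that in mind.

## Prognostic statistics

Continuous effects are reported on the interquartile scale: the
odds/hazard ratio factor exp(β·(Q3 − Q1)) for moving a feature from
its 1st to its 3rd quartile, with the 95% CI scaled the same way.
Binary categorical features are reported for the level change itself.

* **Association**: Mann-Whitney two-sided rank test (exact for small
  tie-free samples, tie-corrected normal approximation otherwise);
  effect size r² = Z²/N with Z recovered from the two-sided p-value.
* **Logistic**: maximum-likelihood fit; feature significance by the
  likelihood-ratio test dropping the feature; univariate AUC is the
  rank AUC of the feature itself, multivariate AUC the model's.
  Non-convergence and separation raise an explicit failure, never
  silent numbers.
* **Cox**: partial-likelihood fit (lifelines).  Univariate p-values
  use Rao's score test at β = 0, computed directly from the risk sets
  with the Breslow convention; for a single binary covariate with
  untied event times this is numerically the log-rank test, a property
  the tests verify to 1e-6.  Multivariate p-values are Wald.
* **Validation AUC**: Harrell bootstrap optimism correction of
  Somers' Dxy — apparent Dxy minus the mean over 100 resamples of
  (Dxy of the refit on its resample − Dxy of that refit on the
  original data) — mapped to AUC = (Dxy + 1)/2.  Failed refits are
  skipped with a logged count; more than 50% failures abort.
* **Cutoff stratification**: every observed feature value inside the
  10–90% quantile window (configurable) is tried as a dichotomising
  cutoff; the minimum two-group log-rank p is reported together with
  the corrected value P_cor = −1.63·P_min·(1 + 2.35·ln P_min), valid
  for P_min < 0.1 and clipped to [P_min, 1]; for P_min ≥ 0.1 the
  corrected value is reported missing.
* **Multiple imputation**: m completed tables (default 100);
  continuous columns by predictive-mean matching — a Bayesian draw of
  the regression of the column on the other low-cardinality columns,
  each missing entry replaced by a random draw from its 5 nearest
  observed donors on the predictor scale — and categorical columns by
  a draw from the fitted category frequencies.  Per-imputation
  coefficient estimates are pooled by Rubin's rules (total variance =
  within + (1 + 1/m)·between, t reference with Rubin's degrees of
  freedom); rank-test outputs are pooled as the median p and median r²
  across imputations.

The cohort filter drops cases flagged for a missing 5-year metastasis
status, clinical metastasis at diagnosis, or a tumor-free section, and
logs the count removed per rule.  Multivariate analyses adjust for
differentiation (well/moderate merged vs poor), histological type,
T stage, and — for the two-institute binary outcome analysis — the
cohort indicator.

## The synthetic-data generator

Six connection-frequency archetypes stand in for the six tissue
phenotypes the method discovers on real slides.  Each archetype is
defined by a cell mixture p over (M, I, S, N); its target spectrum is
the pair distribution induced by independent type marks, f_ij = 2
p_i p_j (i ≠ j), f_ii = p_i², so the direct Dirichlet sampler and the
geometric slide generator share one ground truth.  The default
mixtures and densities (cells per 200 µm tile) are

| archetype | M | I | S | N | density |
|---|---|---|---|---|---|
| tumor | 0.88 | 0.08 | 0.04 | 0 | 350 |
| smooth_muscle | 0.01 | 0.04 | 0.95 | 0 | 150 |
| inflammation | 0.08 | 0.86 | 0.06 | 0 | 450 |
| stroma | 0.10 | 0.25 | 0.65 | 0 | 200 |
| tumor_stroma_interface | 0.45 | 0.12 | 0.43 | 0 | 300 |
| necrosis | 0.25 | 0.12 | 0.08 | 0.55 | 250 |

giving a minimum pairwise chi-squared distance of 0.53 between
spectra.  Densities are in the range of H&E tile cell counts at 20×
magnification.  The direct sampler draws Dirichlet vectors with mean
equal to the target spectrum and a single concentration scalar
(default 150) controlling cluster tightness; zero-support components
stay exactly zero.  Slides place cells by a homogeneous Poisson
process per rectangular region with independent type marks and paint
the mask (default 2.2 µm/pixel, the appearance-segmentation patch
resolution) with the archetype's appearance class.  Cohorts draw the
binary 5-year metastasis outcome from a logistic model and event times
from an exponential proportional-hazards model (baseline 0.08
events/year, administrative censoring at 5 years), with standard
clinical covariates drawn at the marginal frequencies of a
two-institute stage-II colorectal series and completely-at-random
missingness on request.

What the generator does *not* emulate: spatial clustering and
anisotropy of real cell patterns (the Poisson-independent-marks model
makes the expected spectrum computable, which is exactly what the
tests need, but real tiles are clumpier), gradual transitions between
tissue regions, segmentation noise in the mask, informative censoring,
and non-random missingness.  Passing tests therefore demonstrate that
the pipeline recovers known structure of this idealised kind, not that
it would discover the same six phenotypes on real slides.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
geometry and clustering oracles on point sets of n ≤ 8 (500 and 100
random instances), phenotype recovery on 600 tiles (6 × 100), planted
effect recovery at n = 2000 with CI coverage at n = 300 over 100
replicates, and pipeline smoke runs on 6–30 simulated cases.  The
k-selection scan in the analysis scripts uses a 1000-tile subsample
and 20–30 restarts; the final fit always uses the full 100-restart
protocol.  Imputation demonstrations use m = 20; the default remains
m = 100.  All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); the pipeline splits one root seed into
per-stage seeds, and identical configurations reproduce byte-identical
output tables.

## Known limitations

The k-medoids search is exact only against its restart budget; the
oracle guarantee holds for the exhaustive-initialisation mode.  The
O(n²) distance matrix keeps pooled clustering comfortable up to a few
thousand tiles; cohorts of hundreds of slides would need subsampling
(as the analysis scripts do for the k scan) or a chunked backend.  The
mask-based CF ratio numerator counts tissue pixels in whole tiles, so
a tile straddling a tissue boundary contributes only its tissue part —
consistent with the denominators — but mask and tile grids are assumed
axis-aligned in the same µm frame.  The score test implementation uses
the Breslow tie convention; with heavily tied event times it will
differ from the exact log-rank variance.
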