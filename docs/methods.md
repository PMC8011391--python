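# Methods

This note documents the models and procedures `speciesid` implements, the
conventions it fixes where the underlying methods are silent, and what the
synthetic tests do and do not establish.

## Data model

Genotypes are integer-coded: biallelic SNPs as ALT-allele dosage {0,1,2},
dominant markers (AFLP-style presence/absence) as {0,1}, with the sentinel
`MISSING = -1`. One alphabet serves both data types so every downstream
stage is genotyping-method agnostic. Multiallelic VCF records are dropped
along with indels: they do not fit the biallelic dosage code.

Filters follow reduced-representation practice: per-genotype calls with
depth below `min_call_depth` become missing *before* the site-level filters,
then sites failing the call-rate or minor-allele-frequency thresholds are
removed (defaults: ≥ 80% call rate, MAF ≥ 1%). MAF is computed from allele
counts for dosage data and from presence frequency for dominant data. In
dominant data, a cell value of 2 is an anomaly (dominant markers cannot show
heterozygotes); the reader stores the cell as missing and flags the whole
marker, and `filter_dominant_markers` removes flagged markers before
applying the MAF cut. An accession-level `max_missing_rate` filter is
offered as a marker-level proxy for read-count filters that operate upstream
of variant calling.

Imputation replaces each missing cell with the modal non-missing call of its
marker, ties broken toward the lowest code (a deterministic rule is required
for reproducibility; the choice is otherwise arbitrary). This is fast and
class-agnostic but biased toward the majority species — consequences for the
outlier screen are discussed below.

## Distances

Two dissimilarities are used, matching the classifiers they feed:

- **Divergent sites** (1-NN, NJ): the count of markers at which both calls
  are present and differ, with pairwise deletion of missing data. Counts are
  deliberately *not* normalised by the number of comparable sites — this
  reproduces the classic `dist.gene`-style behaviour the comparison design
  assumes. The cost is a downward bias for high-missingness pairs: an
  accession with few called markers looks artificially close to everything.
  Users comparing accessions with very uneven missingness should prefer the
  recorded `comparable_sites` matrix to normalise, or impute first.
- **Euclidean on imputed codes** (conservative 3-NN): the standard k-NN
  metric over the integer dosage codes, requiring a complete matrix.

## Classifiers

All five classify in leave-one-out spirit: a query's own label never counts
as independent evidence beyond what each rule explicitly allows.

**1-NN** adopts the label of the nearest other accession. When several
neighbours tie for nearest, a strict majority among the tied set decides,
else the call is ambiguous (the classic rule leaves ties unspecified; a
deterministic convention is fixed here). 1-NN is the baseline: a mutually
nearest mislabelled pair will swap labels, so methods that cannot beat 1-NN
are unsuitable for curation.

**Conservative 3-NN** includes the query itself (distance 0, carrying its
current label as one vote) among its k=3 neighbours and requires l=2 votes.
Consequences: one agreeing neighbour confirms an a-priori label, two
dissenting neighbours are needed to overturn it, and the minimum species
size for an unambiguous correct confirmation drops from 3 to 2 (this is the
quantity `scripts/acceptance.py` recomputes). Accessions tied with the
third-nearest neighbour all enter the vote. A top-tie at or above l
abstains rather than guessing — consistent with the rule's conservative
intent.

**NJ smallest-subtree**: Saitou–Nei agglomeration implemented directly
(Q-matrix minimisation; ties toward the first accession-index pair; negative
branch lengths clamped to zero with originals kept in diagnostics). Because
clades require a root and NJ trees are unrooted, the tree is midpoint-rooted
before classification; midpoint rooting is deterministic and independent of
input order (ties in the longest path resolve to the lexicographically
smallest leaf pair). For each query the smallest clade properly containing
it votes by strict majority of the *other* leaves; one escalation to the
next enclosing clade is allowed, then the call is ambiguous. Two
conventions are fixed here that tree-reading humans never had to specify:
the rooting (exposed as a config option, midpoint being the only current
choice) and the exclusion of the query's own label from subtree votes (its
classification should not self-confirm).

**Random Forest (OOB)**: an explicit bagging loop over scikit-learn CART
trees — gini impurity, mtry = ⌊√p⌋ features per split, bootstrap with
replacement, 10,000 trees by default. Each accession is called by plurality
over the trees whose bootstrap excluded it; with n accessions that is about
(1−1/n)ⁿ ≈ 36.8% of trees, i.e. ~3,680 of 10,000 — the reason the default
forest is that large. Plurality ties break toward the lexicographically
first species; an accession left in-bag by every tree (only possible in tiny
forests) is reported ambiguous. The bagging loop is deliberately not
delegated to `RandomForestClassifier`: per-tree bootstrap membership is
needed by the OOB aggregation and the proximity screen, and only public
sklearn API is used this way.

**Naive Bayes**: each marker is a categorical variable over its observed
alphabet; class-conditional probabilities are (count + α)/(n_class + α·|alphabet|)
with α=1 by default, priors are class frequencies, posteriors accumulate in
log space. With α=0 a class containing an unseen category drops out with
−∞ log-posterior rather than failing numerically. Leave-one-out prediction
subtracts the query's own counts from the tables (keeping the full-data
alphabet fixed), which is exactly a refit without the query whenever the
query holds no private allele. Posterior ties break lexicographically.
Marker independence is assumed — linkage between markers is disregarded.

Benchmark convention: supervised learners are evaluated the way the
curated-dataset experiment evaluates them — RF by OOB votes, NB by
resubstitution (LOO available and used for unbiased accuracy on complete
collections).

## Outlier screen

Proximity between two accessions is the fraction of trees in which they land
in the same terminal node of a supervised forest (default 50,000 trees).
Two accumulation conventions are offered: over all trees (default) or over
trees where both accessions were out of bag, the two variants in circulation.
Raw outlyingness of accession i is n_class / Σ_j prox(i,j)² over its
labelled classmates (self-proximity excluded; n_class includes i); per class
the raw scores are centred by the median and scaled by the MAD with the
standard consistency constant (≈1.4826); zero MAD falls back to centring
with a warning; scores above 10 are flagged. Singleton classes get an
undefined (NaN) score — reported, never flagged.

The screen is advisory. When missing calls were imputed with the most common
allele, low-coverage accessions of minority species acquire majority-species
alleles and surface as spurious outliers; the screen is especially prone to
false positives under that imputation and should prompt re-examination, not
removal.

## Benchmark and statistics

The benchmark measures whether classifiers *improve a bad dataset*: within
each cell the collection is subsampled to a fixed per-species representation
(2/4/6/8/10), a fraction of labels (6.25%, 12.5%, 18.75% — exact sixteenths,
so rate × N is integral) is corrupted to a uniformly drawn *different*
species, every classifier sees the identical corrupted labels, and
predictions are scored against the true pre-corruption labels (scoring
against the corrupted labels is available for diagnostics). A label-echo
classifier scores exactly 1 − rate, which the harness uses as an analytic
self-check. Seeding is counter-based (master seed + cell coordinates via
`SeedSequence`), so any cell is reproducible in isolation and the grid is
bit-identical under a fixed seed. Classifier failures are recorded as NaN
cells, never abort the grid. The default design (5 × 3 × 5,000 = 75,000
perturbed datasets) is the stated world; tests scale the replicate count
down, not the grid.

Accuracy excludes ambiguous calls from numerator and denominator; an
all-ambiguous result is undefined, not zero. Per-species accuracies guard
against the metric's sensitivity to class imbalance.

Classifier comparison: accuracies are grouped into problems, aligned by
subtracting each problem's mean, and all k·n aligned values are ranked
jointly (mid-ranks on ties). The statistic

T = (k−1)·[Σⱼ R̂²_{·j} − (k n²/4)(k n+1)²] / ([k n (k n+1)(2 k n+1)]/6 − (1/k)·Σᵢ R̂²_{i·})

is referred to χ²_{k−1}; a degenerate denominator yields T=0, p=1. This
aligned variant outperforms plain Friedman for k ≤ 4–5 classifiers, the
regime here. P-values are Finner-adjusted (adjusted_(i) = max_{j≤i} min(1,
1−(1−p_(j))^{m/j})), and a significant omnibus is followed by comparisons
against the highest-mean-accuracy classifier as control, using
z = (R̄_j − R̄_control)/√(k(n+1)/6) on mean aligned ranks with two-sided
normal tails, Finner-adjusted. The χ² and normal references are
approximations: at very small n they are rough (the test suite documents a
|Δp| ≲ 0.12 band against an exhaustive permutation oracle at n=4), and the
calibration check (type-I error within [0.03, 0.07] at nominal 0.05, k=5,
n=15) is the operationally relevant guarantee. Whether the omnibus test
runs once over all cells or per misclassification-rate group is a user
choice; per-group is the default.

## Synthetic data

The generator draws, per marker, an ancestral frequency p ~ Uniform(0.1,
0.9), per species a frequency p_s ~ Beta(p(1−F)/F, (1−p)(1−F)/F) — the
Balding–Nichols model, in which F is the expected FST between species — and
genotypes Binomial(2, p_s) (or Bernoulli(p_s) for dominant markers), with an
iid missingness mask (default 5%). Defaults (8 species × 10 accessions,
2,000 markers, F=0.3) emulate the curated-collection scale the benchmark
targets. The tests verify that Weir–Cockerham θ estimated from generated
genotypes recovers F.

What the generator does **not** emulate: linkage between markers (making it
flattering to Naive Bayes), within-species population structure,
hybridisation/introgression, and informative missingness (real missingness
concentrates in low-coverage accessions; here it is uniform). A green
synthetic test therefore establishes correctness of the machinery and the
qualitative ordering of methods under clean species structure — not
performance on any particular real collection.

## Numerical and degenerate-input conventions

- Modal-imputation ties → lowest code; NB/RF ties → lexicographic species;
  1-NN nearest ties → strict majority else ambiguous; 3-NN top ties →
  ambiguous; NJ Q-matrix ties → first index pair.
- NJ negative branch lengths clamped to 0, originals retained in
  `diagnostics["negative_branches"]`.
- A pair of accessions with zero comparable sites has no defined
  divergent-site distance: error naming the pair, by design.
- An all-missing marker cannot be imputed: error naming the marker.
- "No sites survive filtering" raises a distinct `EmptyResultError` so
  pipelines can distinguish empty results from malformed input (the CLI
  maps it to exit code 3).
- Rounding of rate × N in label injection is half-up; the stated rates are
  sixteenths, so the products are exact integers at the stated sample sizes.

## Known limitations

- Raw divergent-site counts bias nearest-neighbour searches toward
  high-missingness accessions (see Distances above).
- The RF outlier screen over most-common-allele-imputed data is
  false-positive prone; treat flags as advisory.
- Midpoint rooting is one defensible convention for extracting clades from
  an unrooted NJ tree; trees whose longest path is nearly tied between pairs
  can change ladders under perturbation, though the choice is deterministic
  for any fixed input.
- The Python bagging loop trades speed for bookkeeping transparency;
  at the default 10,000–50,000 trees on thousands of markers, expect
  minutes, not seconds.
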