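# Methods

## Model and assumptions

The package treats a gene's expression across samples as a positive random
variable whose first significant digit carries the signal. For a value
x > 0 the first significant digit is floor(x / 10^floor(log10 x)); its
distribution depends only on the fractional part of log10 x. If that
fractional part is uniform on (0, 1), the digit follows Benford's law,
P(d) = log10(1 + 1/d). For a lognormal gene — log10 x ~ N(μ, σ) — the
fractional part approaches uniformity extremely fast in σ (the deviation
decays like exp(−2π²σ²)), so:

* σ ≳ 0.5 orders of magnitude: the gene is effectively Benford; the
  measured MAE is dominated by sampling noise in the digit frequencies.
* σ ≲ 0.2: the digit distribution concentrates near the digits of 10^μ and
  the MAE is large, with the exact value depending on frac(μ).

This is the mechanism the whole analysis rests on: tissue-specific genes
empirically span multiple orders of magnitude within a tissue, housekeeping
genes do not, so Benford conformity — which never looks at the magnitudes
themselves — separates the two classes.

The conformity score is MAE = (1/9) Σ |A_d − E_d| over the nine digits. It
is zero iff the observed frequencies equal the reference and bounded by 2/9
(the Benford-specific maximum, a point mass on digit 9, is 2(1 − E_9)/9 ≈
0.212). Whole-distribution adherence is tested with the Pearson chi-squared
goodness of fit against counts n·E_d on 8 degrees of freedom, computed from
raw digit counts (the standard GOF construction). The convention is that
p > 0.05 reads as adherence; note that with very many digits (10^5 and up)
the test detects the tiny conditional deviations present in any finite gene
set, so whole-matrix p-values should be read alongside the MAE, which stays
near zero for Benford-like data at any n.

## Digit extraction and numerical choices

Digit extraction is arithmetic (floor(log10), scale, floor), vectorised,
with two safeguards:

* scaling uses multiplication by exactly representable positive powers of
  ten for sub-unity values (dividing 0.7 by 10^−1 yields 6.999…9 in binary
  floating point and would misread the digit), in two steps beyond 10^150
  so extreme exponents cannot overflow;
* a mantissa within 10^−9 of the digit boundary above it is resolved from
  the value's shortest round-trip decimal representation, which defines the
  intended semantics (a value that prints as 0.7 has first digit 7). The
  test suite checks the arithmetic path against a string-based oracle over
  1e−8..1e12.

Zeros are always excluded from digit tabulation and tallied separately;
negative values raise an error rather than being skipped, since expression
data is non-negative by construction and a negative signals corrupt input.
The `exclude_below_one` flag additionally drops values in (0, 1) — off by
default, intended for per-million-scaled metrics where lowly expressed
genes produce sub-unity decimals. A gene or pooled category with no usable
values yields an explicit undefined result (an error on access, a flagged
row in individual-centric tables) instead of NaN propagation, because
all-zero genes inherently deviate from the law and must be filtered
deliberately.

Ties and ordering are deterministic throughout: gene ranking breaks MAE
ties by identifier; KNN orders neighbour candidates by (distance, gene id);
the expressed-gene filter includes every gene whose mean CPM equals the
threshold order statistic (the k-th largest mean, k = ceil(fraction · n)).

## Normalisation metrics

CPM, RPKM and TPM follow their standard definitions (per-sample totals of
10^6; RPKM additionally per kilobase of gene length; TPM renormalising
per-kilobase rates to 10^6 per sample). Gene lengths are user-supplied
exonic lengths; no annotation parsing. Log-scale cutoffs quoted as
"log2 CPM" thresholds are interpreted as log2(CPM + 1); the offset is
configurable in `log2_transform`. Matrices carry a metric tag, and every
scoring operation refuses `log2` input outright: log transformation removes
the order-of-magnitude spread the first-digit law reflects, and scoring it
silently would be a correctness trap.

## Classification

Features are the nine digit frequencies plus the MAE, used unscaled — all
ten components live in [0, 1] and are commensurate; a standardisation step
was considered and rejected as unnecessary. Visualisation uses classical
(Torgerson) metric MDS on Euclidean distances: double-centre the squared
distance matrix, eigendecompose, keep the top axes scaled by the square
roots of their (clipped non-negative) eigenvalues. Coordinates are centred
and made deterministic by a sign convention; tests assert distance
preservation rather than coordinates. A leading-fold-change MDS of the kind
expression packages provide is deliberately not used: its distances are
defined on expression profiles, not digit-frequency vectors.

KNN uses Euclidean distance with majority vote among k = 7 by default
(k ∈ {3, 5, 7, 9} is worth scanning; with two classes and odd k vote ties
cannot occur, and even k warns and breaks vote ties toward the
tissue-specific class). Distance ties are broken by gene id, making
predictions invariant under training-row permutation — randomised
tie-breaking, as some KNN implementations use, would not be reproducible.
The train/test split is stratified 70:30 with a mandatory seed. Sensitivity
TP/(TP+FN) and specificity TN/(TN+FP) take tissue-specific as the positive
class; the confusion grid has actual rows and predicted columns, ordered
(housekeeping, tissue_specific).

## Synthetic data: what it emulates, what it does not

`generate_expression` draws, per gene g in category c, a location
μ_g ~ U(category's log10 range) and values 10^N(μ_g, σ_c) across samples —
lognormal parameterised in log10 so σ is directly "orders of magnitude
spanned". Defaults model a bulk-tissue study: 1000 samples (per-gene digit
distributions need on the order of a thousand observations to be stable)
and three 300-gene categories:

| category        | log10 μ range | σ (log10) | behaviour            |
|-----------------|---------------|-----------|----------------------|
| housekeeping    | (1.5, 3.5)    | 0.15      | Benford-violating    |
| tissue_specific | (0.5, 3.5)    | 1.0       | Benford-adhering     |
| random          | (0.5, 3.5)    | 0.5       | near the noise floor |

σ values are chosen to reproduce the *ordering* of category MAE
distributions, not any particular magnitude — published density plots give
no quantitative dynamic-range figures to match. Location ranges span an
integer number of decades so that frac(μ) is exactly uniform within each
category and the pooled matrix is Benford in expectation; a set-wide-narrow
housekeeping variant (range span < 1 decade), which additionally elevates
the *individual-centric* housekeeping MAE, is exercised with a dedicated
configuration in the tests. Optional layers: uniform zero inflation (each
cell zeroed independently — deliberately cruder than expression-dependent
dropout, which is a non-goal), Poisson count sampling (preserves the digit
pattern for means ≳ 10), and binomial thinning of integer counts as the
count-level analogue of sequencing at reduced depth. `generate_benford_exact`
draws 10^U(0, orders), whose digits follow the law exactly in expectation;
it anchors the chi-squared calibration check.

Passing tests on this generator demonstrate that the pipeline recovers the
dynamic-range mechanism and the resulting class separation under the stated
lognormal model. They do not demonstrate robustness to features of real
data the generator omits: library-size variation across samples, gene-gene
correlation, expression-dependent dropout, overdispersion beyond Poisson,
or batch structure.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (`numpy.random.default_rng`);
identical configuration plus seed reproduces matrices bit for bit and CLI
outputs byte for byte. The bundled checks run at desk scale by design: ten
replicates of the 900 × 1000 preset for the mechanism and classifier
checks, 1000 replicates of n = 5000 for chi-squared calibration, and a
2000 × 100 count matrix for the thinning/log-transform comparisons.

## Known limitations

* Individual-centric scoring reflects the *set-wide* spread of a category
  within a sample, so category composition (the μ range), not only
  per-gene σ, drives it; the two modes answer different questions.
* MAE on few digits is noisy; a warning fires below 50 usable values per
  gene, but the package does not model the sampling distribution of MAE.
* Chi-squared conformity at very large digit counts rejects negligible
  deviations; no effect-size-aware alternative (e.g. a distortion factor)
  is provided.
* Only first-digit analysis is implemented — no second-digit or digit-pair
  tests, and no alternative conformity statistics.
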