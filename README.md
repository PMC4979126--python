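# benfordrna

Benford first-digit conformity analysis of digital gene expression.

## The problem

Benford's law (the first-digit law) states that in many naturally occurring
count-rich datasets the leading decimal digit *d* appears with probability

    E_d = log10(1 + 1/d),    d = 1..9

so digit 1 leads about 30.1% of the time and digit 9 under 5%. RNA-seq
expression values are approximately lognormal and span several orders of
magnitude, so pooled over a transcriptome they follow the law closely — but
*individual genes* differ. A gene whose expression varies widely across
samples (typically tissue-specific) adheres to Benford; a gene held in a
narrow range (typically housekeeping) deviates strongly. This package scores
that per-gene deviation and turns it into a predictor of tissue specificity,
for anyone with a gene × sample count matrix (bulk tissue panels or
single-cell data) and no interest in the expression magnitudes themselves.

## The statistic

Conformity is measured by the mean absolute error between observed first-digit
frequencies *A_d* and the Benford expectation:

    MAE = (1/9) Σ_{d=1..9} |A_d − E_d|

computed in two modes: **gene-centric** (one MAE per gene, digits pooled
across samples) and **individual-centric** (one MAE per sample per gene
category, digits pooled within the sample). Whole-distribution adherence is
tested with a Pearson chi-squared goodness of fit on 8 degrees of freedom
(p > 0.05 read as adherence). Zeros never contribute a digit; values below 1
can be excluded for per-million-scaled metrics (CPM/TPM), whose sub-unity
decimals otherwise distort the pattern. Per-gene digit frequencies plus the
MAE give a 10-dimensional feature vector used for MDS visualisation and
k-nearest-neighbour classification of housekeeping vs. tissue-specific genes
(k = 7, Euclidean distance, stratified 70:30 split).

Everything is exercised end to end on a bundled synthetic generator: per-gene
lognormal expression with category-specific dynamic range (narrow σ for
housekeeping, wide σ for tissue-specific), optional zero inflation, Poisson
count sampling, and binomial thinning to emulate reduced sequencing depth.

## Worked example

```python
import benfordrna as br

# simulate a bulk-tissue style dataset: 900 genes x 1000 samples
config = br.preset_config("gtex-lung-like", seed=42)
matrix, labels = br.generate_expression(config)

# whole-matrix first-digit distribution
dist = br.digit_distribution(matrix.values)
print(f"digit-1 frequency: {dist.frequencies[0]:.4f} (Benford expects 0.3010)")
print(f"whole-matrix MAE:  {br.mae(dist):.4f}")

# gene-centric conformity scores by category
table = br.gene_centric_mae(matrix)
frame = table.table.assign(category=table.table["gene_id"].map(labels))
print(frame.groupby("category")["mae"].median().round(4))

# KNN prediction of tissue specificity from digit features
features = br.build_features(table, labels)
keep = features.frame["label"].isin(["housekeeping", "tissue_specific"])
features = features.subset(list(features.frame.index[keep]))
train, test = br.split_train_test(features, train_fraction=0.7, seed=42)
report = br.knn_classify(train, test, k=7)
print(f"sensitivity {report.sensitivity:.2f}, specificity {report.specificity:.2f}")
```

prints

```
digit-1 frequency: 0.2987 (Benford expects 0.3010)
whole-matrix MAE:  0.0014
category
housekeeping       0.0891
random             0.0074
tissue_specific    0.0073
sensitivity 1.00, specificity 1.00
```

The matrix as a whole is essentially Benford (MAE 0.0014, digit 1 at 29.9%),
yet the narrow-range housekeeping genes score an order of magnitude worse
than tissue-specific genes (median MAE 0.089 vs. 0.007) — and that gap alone
lets a KNN classifier separate the two classes on the held-out 30%.

The same pipeline is available from the shell:

```sh
benfordrna simulate --preset gtex-lung-like --seed 1 --out sim/
benfordrna digits   --input sim/matrix.tsv --out digits/
benfordrna score    --input sim/matrix.tsv --mode gene --out score/
benfordrna classify --score-table score/mae_table.tsv \
                    --labels sim/labels.tsv --k 7 --seed 1 --out clf/
```

Matrices are read and written as dense TSV/CSV (gene rows, sample columns)
or MatrixMarket `.mtx` with one-id-per-line sidecar files.

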