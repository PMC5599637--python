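# ratiolink

Scale-free pairwise peak-ratio features for deciding whether two
chromatographic (GC-MS) profiles originate from the same production batch.

## The problem

Forensic laboratories compare seized drug specimens — e.g. cocaine, profiled
by the integrated GC-MS peak areas of eight alkaloid target compounds — to
decide whether two specimens are *linked* (same production batch) or
*unlinked*. The traditional approach computes a single Pearson correlation
between the two whole profiles and thresholds it. That implicitly assumes all
compounds are stable: if even one compound degrades during storage, row
normalization spreads the damage into every normalized peak, and the
correlation-based comparison suffers.

`ratiolink` implements a normalization-free alternative. For a profile with
peaks $x_1,\dots,x_k$ it forms every pairwise ratio

$$r_{ab} = \frac{x_a}{x_a + x_b},\qquad 1 \le a < b \le k,$$

giving $k(k-1)/2$ values in $[0,1]$ (28 for 8 peaks, 66 for 12). A pair of
profiles is described by the absolute ratio differences
$\mathrm{rd}_{ab} = |r_{ab}^{(1)} - r_{ab}^{(2)}|$. Ratios are invariant to
any positive rescaling of a profile, so instrument response, sample amount
and normalization all cancel — and an unstable compound only perturbs the
ratios it takes part in, leaving the other ratios untouched. A random forest
(or logistic regression) trained on pairs with known linkage then learns
which ratios are informative and predicts $P(\text{unlinked})$ for new pairs;
performance is summarized by the Matthews correlation coefficient

$$\mathrm{MCC} = \frac{TP\cdot TN - FP\cdot FN}
{\sqrt{(TP{+}FP)(TP{+}FN)(TN{+}FP)(TN{+}FN)}},$$

which stays meaningful under the extreme linked/unlinked imbalance
(positive class = unlinked).

The package also ships the two baselines (Pearson distance $(1-r)/2$ and
per-compound normalized peak differences $|x_1-x_2|/(x_1+x_2)$), three
per-peak transformations (none, fourth root, log1p), a noise-injection
stress test that appends peaks resampled from the dataset's own values, a
synthetic generator of grouped batch profiles with known ground truth, and a
grid runner that evaluates every transform × feature × classifier
combination internally (5-fold CV or out-of-bag) and externally (held-out
validation groups).

## Worked example

Generate a stressed synthetic dataset (10 training batches of ~5 specimens
plus 20 unrelated singles, 6 validation batches, two compounds degrading at
20 %/month over 0–15 months of storage), inject 4 noise peaks, and compare
the ratio features against the Pearson baseline:

```bash
cat > cfg.yaml <<EOF
n_train_groups: 10
n_train_group_samples_total: 50
n_singles: 20
n_valid_groups: 6
n_valid_samples_total: 30
unstable_compounds: [0, 1]
degradation_rate: 0.2
EOF
ratiolink simulate --config cfg.yaml --out peaks.csv --seed 7
ratiolink run-grid --peaks peaks.csv --transforms none \
    --features pearson,ratio_diff --classifiers logistic,random_forest \
    --noise-peaks 4 --replicates 3 --out-dir grid --seed 11
```

`grid/grid_summary.csv` then contains (mean over the 3 replicate seeds):

```
noise_peaks transform feature_method    classifier  internal_mcc_mean  external_mcc_mean
          4      none        pearson      logistic           0.000000           0.000000
          4      none        pearson random_forest           0.037631           0.058114
          4      none     ratio_diff      logistic           0.996938           1.000000
          4      none     ratio_diff random_forest           0.998456           0.972715
```

The single Pearson distance collapses under the injected noise (MCC ≈ 0
means no better than guessing), while the 66 ratio differences still
separate linked from unlinked pairs almost perfectly, both in training
(internal, cross-validation/out-of-bag) and on the untouched validation
batches (external). `ratiolink validate` prints the underlying confusion
counts for one cell:

```
external MCC = 0.9727 (TP=370 TN=62 FP=3 FN=0)
```

i.e. 370 unlinked validation pairs correctly called unlinked, 62 linked
pairs correctly called linked, 3 linked pairs missed, no false links.
Variable importance shows *why* it works — the forest's mean decrease in
out-of-bag accuracy concentrates on ratios of two real compounds
(mean 3.7e-3) and ignores every ratio touching a noise peak (mean 1e-5):

```bash
ratiolink importance --peaks peaks.csv --noise-peaks 4 --out importance.csv --seed 11
```

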