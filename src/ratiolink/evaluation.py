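"""Performance evaluation: MCC, internal/external protocols, and the model grid.

Linked/unlinked pair data are extremely imbalanced (unlinked pairs vastly
outnumber linked ones), so performance is summarized with the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with "unlinked" as the positive class.  MCC is 1 for a perfect prediction
(FP = FN = 0), 0 for a random one, and -1 for total disagreement; when any
marginal is empty the denominator vanishes and the value is defined as 0.

Internal (training-set) performance uses stratified 5-fold cross-validation
for logistic regression and the built-in out-of-bag votes for random
forests.  External performance applies the fitted model, untouched, to
held-out validation pairs.  :func:`run_grid` sweeps the full model grid
(transform x feature representation x classifier), optionally with and
without injected noise peaks, over replicate seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, KFold

from ratiolink import modeling
from ratiolink.features import FEATURE_METHODS, PairFeatureMatrix, build_feature_matrix
from ratiolink.modeling import ClassifierSpec, FitResult, ModelError, classify
from ratiolink.noise import NoiseSpec, add_noise_peaks
from ratiolink.pairing import LINKED, UNLINKED, enumerate_pairs
from ratiolink.profiles import ProfileSet, TransformKind, preprocess


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts with unlinked as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a confusion table, in [-1, 1].

    Computed in floating point with a factored denominator so counts of
    ~1e4 pairs cannot overflow; a zero marginal yields 0 by convention.
    """
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom_factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(f == 0 for f in denom_factors):
        return 0.0
    numerator = tp * tn - fp * fn
    denominator = math.sqrt((tp + fp) * (tp + fn)) * math.sqrt((tn + fp) * (tn + fn))
    return max(-1.0, min(1.0, numerator / denominator))  # guard last-ulp overshoot


def confusion_from_labels(true: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """Count TP/TN/FP/FN treating "unlinked" as positive."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise ValueError("true and predicted labels must align")
    pos_t = true == UNLINKED
    pos_p = predicted == UNLINKED
    return ConfusionCounts(
        tp=int((pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
    )


def cross_validate(
    features: PairFeatureMatrix,
    spec: ClassifierSpec,
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> ConfusionCounts:
    """Stratified k-fold cross-validation for the logistic classifier.

    Each fold is predicted by a model fitted on the other k-1 folds;
    the per-fold confusion counts are pooled.  Random forests estimate
    internal performance via :func:`oob_evaluate` instead.
    """
    if spec.method != "logistic":
        raise ModelError("cross_validate is for logistic regression; use oob_evaluate for forests")
    y = features.labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ModelError(
            f"each class needs >= k={k} pairs for {k}-fold CV "
            f"(have {counts.to_dict()}); use more data or fewer folds"
        )
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=k, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for train_idx, test_idx in splitter.split(features.X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ModelError("a CV fold lost a class; use more data or fewer folds")
        fold_train = PairFeatureMatrix(
            method=features.method,
            X=features.X.iloc[train_idx].reset_index(drop=True),
            pairs=features.pairs.iloc[train_idx].reset_index(drop=True),
            labels=features.labels.iloc[train_idx].reset_index(drop=True),
        )
        fold_test = PairFeatureMatrix(
            method=features.method,
            X=features.X.iloc[test_idx].reset_index(drop=True),
            pairs=features.pairs.iloc[test_idx].reset_index(drop=True),
            labels=features.labels.iloc[test_idx].reset_index(drop=True),
        )
        model = modeling.fit(fold_train, spec)
        pred = classify(modeling.predict_proba(model, fold_test), spec.threshold)
        c = confusion_from_labels(y[test_idx], pred)
        tp, tn, fp, fn = tp + c.tp, tn + c.tn, fp + c.fp, fn + c.fn
    return ConfusionCounts(tp, tn, fp, fn)


def oob_evaluate(model: FitResult) -> ConfusionCounts:
    """Out-of-bag confusion counts for a fitted random forest.

    Uses only training pairs that received at least one out-of-bag vote;
    with very few trees some pairs have none, which is reported as an
    error rather than silently dropped wholesale.
    """
    if model.spec.method != "random_forest":
        raise ModelError("oob_evaluate requires a random-forest fit")
    oob = model.oob_decision
    covered = ~np.isnan(oob)
    n_uncovered = int((~covered).sum())
    if covered.sum() == 0:
        raise ModelError("no training pair has out-of-bag votes; increase n_trees")
    if n_uncovered > 0.5 * len(oob):
        raise ModelError(
            f"{n_uncovered}/{len(oob)} training pairs lack out-of-bag votes; "
            "increase n_trees for a usable OOB estimate"
        )
    pred = classify(oob[covered], model.spec.threshold)
    return confusion_from_labels(model.train_labels.to_numpy()[covered], pred)


def external_validate(model: FitResult, validation_features: PairFeatureMatrix) -> ConfusionCounts:
    """Confusion counts of the fitted model on held-out validation pairs (never refits)."""
    if validation_features.n_pairs == 0:
        raise ModelError("validation feature matrix is empty")
    probs = modeling.predict_proba(model, validation_features)
    pred = classify(probs, model.spec.threshold)
    return confusion_from_labels(validation_features.labels.to_numpy(), pred)


def _internal_counts(
    features: PairFeatureMatrix, model: FitResult, spec: ClassifierSpec, seed: int
) -> ConfusionCounts:
    if spec.method == "logistic":
        return cross_validate(features, spec, k=5, seed=seed)
    return oob_evaluate(model)


def run_grid(
    train: ProfileSet,
    valid: ProfileSet,
    transforms: Sequence[TransformKind | str] = tuple(TransformKind),
    feature_methods: Sequence[str] = FEATURE_METHODS,
    classifier_specs: Sequence[ClassifierSpec] | None = None,
    replicates: int = 1,
    seed: int = 0,
    noise_conditions: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Evaluate every (noise, transform, feature, classifier) cell of the grid.

    For each replicate a fresh seed drives noise injection and classifier
    fitting.  Internal performance comes from cross-validation (logistic)
    or out-of-bag votes (random forest); external performance from the
    held-out validation profiles.  Returns a tidy frame with one row per
    cell and replicate; a failing cell is recorded with an ``error``
    message rather than dropped.
    """
    if classifier_specs is None:
        classifier_specs = (ClassifierSpec("logistic"), ClassifierSpec("random_forest"))
    transforms = [TransformKind(t) for t in transforms]
    if not (transforms and feature_methods and classifier_specs and replicates >= 1):
        raise ValueError("grid axes and replicates must be non-empty")

    # one independent child seed per replicate, fanned out to stages
    rep_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(replicates) % (2**31)]

    rows = []
    for n_noise in noise_conditions:
        for rep, rep_seed in enumerate(rep_seeds):
            train_n, valid_n = _inject_noise_jointly(train, valid, n_noise, rep_seed)
            train_pairs = enumerate_pairs(train_n, "train")
            valid_pairs = enumerate_pairs(valid_n, "validation")
            for t in transforms:
                train_pp = preprocess(train_n, t)
                valid_pp = preprocess(valid_n, t)
                for fm in feature_methods:
                    feats_train = build_feature_matrix(train_pp, train_pairs, fm)
                    feats_valid = build_feature_matrix(valid_pp, valid_pairs, fm)
                    for cspec in classifier_specs:
                        row = {
                            "noise_peaks": n_noise,
                            "transform": t.value,
                            "feature_method": fm,
                            "classifier": cspec.method,
                            "replicate": rep,
                            "seed": rep_seed,
                        }
                        try:
                            rspec = ClassifierSpec(
                                method=cspec.method,
                                threshold=cspec.threshold,
                                n_trees=cspec.n_trees,
                                seed=rep_seed,
                            )
                            model = modeling.fit(feats_train, rspec, transform=t)
                            internal = _internal_counts(feats_train, model, rspec, rep_seed)
                            external = external_validate(model, feats_valid)
                            row["internal_mcc"] = mcc(internal)
                            row["external_mcc"] = mcc(external)
                            row["error"] = ""
                        except Exception as exc:  # record, keep sweeping
                            row["internal_mcc"] = np.nan
                            row["external_mcc"] = np.nan
                            row["error"] = f"{type(exc).__name__}: {exc}"
                        rows.append(row)
    return pd.DataFrame(rows)


def _inject_noise_jointly(
    train: ProfileSet, valid: ProfileSet, n_noise: int, seed: int
) -> tuple[ProfileSet, ProfileSet]:
    """Inject noise with a pool spanning both splits, then split back."""
    if n_noise == 0:
        return train, valid
    combined = ProfileSet(
        peaks=pd.concat([train.peaks, valid.peaks]),
        meta=pd.concat([train.meta, valid.meta]),
        noise_compounds=train.noise_compounds,
    )
    noisy = add_noise_peaks(combined, NoiseSpec(n_noise_peaks=n_noise, seed=seed))
    return noisy.subset("train"), noisy.subset("validation")


def summarize_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate rows: mean and SEM of internal/external MCC per cell.

    SEM is across replicate seeds and absent (NaN) for a single replicate.
    """
    keys = ["noise_peaks", "transform", "feature_method", "classifier"]

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for col in ("internal_mcc", "external_mcc"):
            vals = g[col].dropna()
            out[f"{col}_mean"] = vals.mean()
            out[f"{col}_sem"] = (
                vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        out["n_replicates"] = int(g[col].notna().sum())
        out["n_failed"] = int((g["error"] != "").sum())
        return pd.Series(out)

    return grid.groupby(keys, as_index=False).apply(_agg, include_groups=False)
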