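"""Binary pair classifiers: logistic regression and random forest.

Both predict P(unlinked) -- the probability that a pair of profiles comes
from different batches; "unlinked" is the positive class throughout.  A
probability at or above the decision threshold (default 0.5) is called
unlinked; the tie goes to unlinked, the conservative call in a forensic
setting.

Logistic regression is unpenalized by default.  On separable data the
maximum-likelihood fit diverges; we then fall back to a weak ridge penalty
and warn.  The random forest uses 500 trees, sqrt(n_features) candidate
features per split, and keeps the out-of-bag votes so internal performance
can be read off without a held-out set.

Variable importance: absolute coefficients for logistic regression;
permutation importance (mean decrease in classification accuracy) for the
random forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from ratiolink.features import PairFeatureMatrix
from ratiolink.pairing import LINKED, UNLINKED
from ratiolink.profiles import TransformKind

#: weak ridge fallback (inverse regularization strength) for separable data
_RIDGE_FALLBACK_C = 1e4


class ModelError(ValueError):
    """Raised for invalid classifier configuration or inputs."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to fit and how."""

    method: str = "random_forest"  # "logistic" or "random_forest"
    threshold: float = 0.5
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("logistic", "random_forest"):
            raise ModelError(f"unknown classifier method {self.method!r}")
        if not 0 < self.threshold < 1:
            raise ModelError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.n_trees < 1:
            raise ModelError("n_trees must be >= 1")


@dataclass
class FitResult:
    """A fitted pair classifier with its provenance.

    ``oob_decision`` holds per-training-pair out-of-bag P(unlinked) for
    random forests (NaN where a pair was in every tree's bootstrap sample);
    absent for logistic regression.
    """

    spec: ClassifierSpec
    feature_method: str
    transform: TransformKind | None
    model: object
    feature_names: list[str]
    train_labels: pd.Series
    oob_decision: np.ndarray | None = None
    _train_X: pd.DataFrame | None = field(default=None, repr=False)
    _importance: pd.Series | None = field(default=None, repr=False)


def _encode(labels: pd.Series) -> np.ndarray:
    bad = set(labels.unique()) - {LINKED, UNLINKED}
    if bad:
        raise ModelError(f"unknown label value(s): {sorted(bad)}")
    return (labels == UNLINKED).to_numpy(dtype=int)


def fit(features: PairFeatureMatrix, spec: ClassifierSpec, transform=None) -> FitResult:
    """Fit the classifier on a pair-feature matrix. Deterministic given spec.seed."""
    y = _encode(features.labels)
    if len(np.unique(y)) < 2:
        raise ModelError("training pairs must contain both linked and unlinked labels")
    X = features.X.to_numpy(dtype=float)

    oob = None
    if spec.method == "logistic":
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            warnings.warn(
                "unpenalized logistic regression did not converge (data may be "
                f"separable); refitting with a weak ridge penalty (C={_RIDGE_FALLBACK_C:g})",
                stacklevel=2,
            )
            model = LogisticRegression(
                penalty="l2", C=_RIDGE_FALLBACK_C, solver="lbfgs", max_iter=1000
            )
            model.fit(X, y)
    else:
        model = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features="sqrt",
            oob_score=True,
            random_state=spec.seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            # few trees can leave pairs without OOB votes; surfaced via NaN rows
            warnings.simplefilter("ignore", UserWarning)
            model.fit(X, y)
        # column order follows model.classes_ = [0, 1]; take P(unlinked).
        # Rows without any OOB vote come back all-zero; mark them NaN.
        decision = model.oob_decision_function_
        oob = decision[:, list(model.classes_).index(1)].copy()
        oob[decision.sum(axis=1) == 0] = np.nan

    return FitResult(
        spec=spec,
        feature_method=features.method,
        transform=transform,
        model=model,
        feature_names=features.feature_names,
        train_labels=features.labels.copy(),
        oob_decision=oob,
        _train_X=features.X.copy(),
    )


def _check_schema(result: FitResult, features: PairFeatureMatrix) -> None:
    if features.feature_names != result.feature_names:
        missing = [c for c in result.feature_names if c not in features.feature_names]
        extra = [c for c in features.feature_names if c not in result.feature_names]
        raise ModelError(
            "feature columns do not match training schema "
            f"(missing: {missing or 'none'}; extra: {extra or 'none'}; "
            "order must match by name)"
        )


def predict_proba(result: FitResult, features: PairFeatureMatrix) -> np.ndarray:
    """P(unlinked) for every pair; columns must match the training schema."""
    _check_schema(result, features)
    proba = result.model.predict_proba(features.X.to_numpy(dtype=float))
    return proba[:, list(result.model.classes_).index(1)]


def classify(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Map P(unlinked) to labels: p >= threshold -> unlinked, else linked."""
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ModelError("probabilities must lie in [0, 1]")
    return np.where(probs >= threshold, UNLINKED, LINKED)


def _forest_mean_decrease_accuracy(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Per-tree out-of-bag permutation importance, averaged over trees.

    For every tree: score its out-of-bag samples, then re-score them with
    one feature's values permuted; the importance of that feature is the
    mean accuracy decrease across all trees.  This is the classical forest
    importance (mean decrease in accuracy) and, unlike permuting through
    the whole ensemble at once, it is not masked by correlated features:
    each tree is probed on its own, so a feature a tree relied on shows up
    even when the rest of the forest can compensate.
    """
    rng = np.random.default_rng(seed)
    n_samples, n_features = X.shape
    n_bootstrap = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
    decreases = np.zeros(n_features)
    for tree in forest.estimators_:
        oob_idx = _generate_unsampled_indices(tree.random_state, n_samples, n_bootstrap, None)
        if oob_idx.size == 0:
            continue
        X_oob, y_oob = X[oob_idx], y[oob_idx]
        base_acc = (tree.predict(X_oob) == y_oob).mean()
        # features this tree never splits on contribute exactly 0
        used = np.unique(tree.tree_.feature)
        for j in used[used >= 0]:
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob_idx.size), j]
            decreases[j] += base_acc - (tree.predict(X_perm) == y_oob).mean()
    return decreases / len(forest.estimators_)


def save_model(result: FitResult, path) -> None:
    """Persist a fit result (classifier, schema, provenance) to ``path``.

    The archive records the package version and feature schema; loading a
    model whose schema no longer matches the features at prediction time
    fails loudly in :func:`predict_proba`.
    """
    import pickle

    import ratiolink

    payload = {
        "format_version": 1,
        "package_version": ratiolink.__version__,
        "result": result,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> FitResult:
    """Load a fit result written by :func:`save_model`."""
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != 1:
        raise ModelError(f"unsupported model archive version: {payload.get('format_version')}")
    return payload["result"]


def importance(result: FitResult) -> pd.Series:
    """Per-feature importance, name-indexed, cached on the fit result.

    Logistic: |coefficient| (intercept excluded).  Random forest: mean
    decrease in out-of-bag classification accuracy when the feature is
    permuted, averaged per tree, seeded from the classifier seed.
    """
    if result._importance is not None:
        return result._importance
    if result.spec.method == "logistic":
        imp = pd.Series(np.abs(result.model.coef_[0]), index=result.feature_names)
    else:
        decreases = _forest_mean_decrease_accuracy(
            result.model,
            result._train_X.to_numpy(dtype=float),
            _encode(result.train_labels),
            seed=result.spec.seed,
        )
        imp = pd.Series(decreases, index=result.feature_names)
    result._importance = imp
    return imp
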