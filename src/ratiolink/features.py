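"""Per-pair comparison features for profile linkage.

Three representations of "how different are these two profiles":

* **Pearson distance** -- the traditional single summary, ``(1 - r) / 2``
  over the two peak vectors, in [0, 1].
* **Single peak differences** -- one value per compound,
  ``|x1 - x2| / (x1 + x2)``, computed on normalized peaks.
* **Pairwise-ratio differences** -- for every unordered compound pair
  (a, b) the scale-free ratio ``a / (a + b)`` is computed per profile and
  the feature is the absolute difference of the two ratios.  With k peaks
  there are k(k-1)/2 ratios (28 for 8 peaks, 66 for 12).  Because a ratio
  of two compounds is unchanged by any rescaling or row normalization of a
  profile, ratios between stable compounds are immune to unstable peaks
  elsewhere in the profile -- the property the whole method rests on.

Conventions: a 0/0 ratio or peak difference is defined as 0 (two absent
peaks are identical); the ratio numerator is the compound that comes first
in canonical compound order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ratiolink.pairing import ProfilePair
from ratiolink.profiles import PeakProfile, PeakTableError, ProfileSet

FEATURE_METHODS = ("pearson", "peak_diff", "ratio_diff")


def n_ratios(n: int) -> int:
    """Number of unordered peak pairs, n(n-1)/2; requires n >= 2."""
    if n < 2:
        raise ValueError(f"need at least 2 peaks to form ratios, got {n}")
    return n * (n - 1) // 2


def ratio_pair_names(compounds: Sequence[str]) -> list[tuple[str, str]]:
    """Canonical unordered compound pairs (earlier compound first)."""
    return [
        (compounds[i], compounds[j])
        for i in range(len(compounds))
        for j in range(i + 1, len(compounds))
    ]


def ratio_feature_names(compounds: Sequence[str]) -> list[str]:
    """Ratio feature column names, ``rd_<A>+<B>``."""
    return [f"rd_{a}+{b}" for a, b in ratio_pair_names(compounds)]


def ratio_involves_noise(compounds: Sequence[str], noise_compounds: Sequence[str]) -> np.ndarray:
    """Boolean mask over canonical ratio coordinates: does the ratio touch a noise peak?"""
    noise = set(noise_compounds)
    return np.array([(a in noise) or (b in noise) for a, b in ratio_pair_names(compounds)])


def _ratio_block(values: np.ndarray) -> np.ndarray:
    """All pairwise ratios a/(a+b) for each row; (n, k) -> (n, k(k-1)/2)."""
    values = np.asarray(values, dtype=float)
    k = values.shape[1]
    iu, ju = np.triu_indices(k, 1)
    a = values[:, iu]
    b = values[:, ju]
    total = a + b
    with np.errstate(invalid="ignore"):
        ratios = np.where(total > 0, a / np.where(total > 0, total, 1.0), 0.0)
    return ratios


def pairwise_ratios(p: PeakProfile) -> pd.Series:
    """The profile's ratio vector a/(a+b) over canonical compound pairs.

    Ranges from 0 (compound a absent) to 1 (only compound a); 0/0 is 0.
    Invariant to any positive rescaling of the profile.
    """
    names = [f"{a}+{b}" for a, b in ratio_pair_names(p.compounds)]
    return pd.Series(_ratio_block(p.values[None, :])[0], index=names)


def pearson_distance(p1: PeakProfile, p2: PeakProfile) -> float:
    """``(1 - r) / 2`` for the Pearson correlation r of the two peak vectors."""
    _check_same_compounds(p1, p2)
    x1, x2 = p1.values, p2.values
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise PeakTableError(
            "Pearson distance undefined for a constant (zero-variance) profile"
        )
    r = np.corrcoef(x1, x2)[0, 1]
    return float((1.0 - r) / 2.0)


@dataclass(frozen=True)
class PairFeatureVector:
    """One pair's feature vector under a given comparison method."""

    method: str
    values: pd.Series
    label: str | None = None


def peak_differences(p1: PeakProfile, p2: PeakProfile) -> PairFeatureVector:
    """Per-compound normalized difference ``|x1 - x2| / (x1 + x2)``, 0/0 -> 0."""
    _check_same_compounds(p1, p2)
    x1, x2 = p1.values, p2.values
    total = x1 + x2
    with np.errstate(invalid="ignore"):
        vals = np.where(total > 0, np.abs(x1 - x2) / np.where(total > 0, total, 1.0), 0.0)
    return PairFeatureVector("peak_diff", pd.Series(vals, index=p1.compounds))


def ratio_differences(p1: PeakProfile, p2: PeakProfile) -> PairFeatureVector:
    """Element-wise ``|ratio1 - ratio2|`` over the canonical ratio coordinates."""
    _check_same_compounds(p1, p2)
    r1 = pairwise_ratios(p1)
    r2 = pairwise_ratios(p2)
    vals = (r1 - r2).abs()
    vals.index = ratio_feature_names(p1.compounds)
    return PairFeatureVector("ratio_diff", vals)


def _check_same_compounds(p1: PeakProfile, p2: PeakProfile) -> None:
    if p1.compounds != p2.compounds:
        raise PeakTableError(
            f"profiles {p1.sample_id!r} and {p2.sample_id!r} have different compounds"
        )


@dataclass(frozen=True)
class PairFeatureMatrix:
    """Per-pair feature vectors plus linkage labels for a comparison method.

    ``X`` holds one row per pair; ``pairs`` carries the sample ids and
    ``labels`` the ground-truth linked/unlinked status, row-aligned with X.
    """

    method: str
    X: pd.DataFrame
    pairs: pd.DataFrame  # columns sample_1, sample_2
    labels: pd.Series  # "linked" / "unlinked"

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.pairs) == len(self.labels)):
            raise ValueError("X, pairs and labels must be row-aligned")
        if not np.isfinite(self.X.to_numpy()).all():
            raise ValueError("pair features must be finite")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.X)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-pair frame: sample_1, sample_2, label, features."""
        out = self.pairs.copy()
        out["label"] = self.labels.to_numpy()
        return pd.concat([out, self.X.reset_index(drop=True)], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_feature_matrix(path: str | Path, method: str) -> PairFeatureMatrix:
    df = pd.read_csv(path, dtype={"sample_1": str, "sample_2": str})
    meta_cols = ["sample_1", "sample_2", "label"]
    return PairFeatureMatrix(
        method=method,
        X=df.drop(columns=meta_cols),
        pairs=df[["sample_1", "sample_2"]],
        labels=df["label"],
    )


def build_feature_matrix(
    pset: ProfileSet, pairs: Sequence[ProfilePair], method: str
) -> PairFeatureMatrix:
    """Compute the chosen comparison for every pair in one vectorized pass.

    ``pset`` should already carry the preprocessing intended for the
    method (for ratio features the row normalization is immaterial, but the
    per-peak transform is not).
    """
    if method not in FEATURE_METHODS:
        raise ValueError(f"unknown feature method {method!r}; expected one of {FEATURE_METHODS}")
    if len(pairs) == 0:
        raise ValueError("no pairs to featurize")

    pos = {sid: i for i, sid in enumerate(pset.sample_ids)}
    i1 = np.array([pos[p.sample_1] for p in pairs])
    i2 = np.array([pos[p.sample_2] for p in pairs])
    values = pset.peaks.to_numpy(dtype=float)

    if method == "pearson":
        centered = values - values.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        if (norms == 0).any():
            sid = np.array(pset.sample_ids)[norms == 0][0]
            raise PeakTableError(
                f"Pearson distance undefined: profile {sid!r} has zero variance"
            )
        r = (centered[i1] * centered[i2]).sum(axis=1) / (norms[i1] * norms[i2])
        X = pd.DataFrame({"pearson_distance": (1.0 - r) / 2.0})
    elif method == "peak_diff":
        x1, x2 = values[i1], values[i2]
        total = x1 + x2
        with np.errstate(invalid="ignore"):
            diffs = np.where(total > 0, np.abs(x1 - x2) / np.where(total > 0, total, 1.0), 0.0)
        X = pd.DataFrame(diffs, columns=[f"pd_{c}" for c in pset.compounds])
    else:
        ratios = _ratio_block(values)
        X = pd.DataFrame(
            np.abs(ratios[i1] - ratios[i2]), columns=ratio_feature_names(pset.compounds)
        )

    pairs_df = pd.DataFrame(
        {"sample_1": [p.sample_1 for p in pairs], "sample_2": [p.sample_2 for p in pairs]}
    )
    labels = pd.Series([p.label for p in pairs], name="label")
    return PairFeatureMatrix(method=method, X=X, pairs=pairs_df, labels=labels)
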