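"""Peak-table I/O, profile containers and preprocessing.

A *profile* is the vector of integrated GC-MS peak areas measured for one
specimen over a fixed list of target compounds.  Profiles are held together
in a :class:`ProfileSet` backed by a pandas DataFrame (rows = samples,
columns = compounds) plus per-sample metadata (batch/group membership and
train/validation split).

Preprocessing follows the profiling convention for this kind of data:

1. scale every profile to a common total area of ``1e6 * n_peaks``;
2. optionally transform each peak (fourth root or log1p);
3. row-normalize so the peaks of a profile sum to one, i.e.
   ``scaled_i = peak_i / sum_j peak_j`` -- injected noise peaks, when
   present, participate in the denominator and therefore perturb every
   normalized peak.

The pipeline is invariant to any positive rescaling of a raw profile, so
instrument response and sample amount cancel out.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: group_id marker for a specimen presumed unrelated to every batch.
SINGLE = "single"

_SPLITS = ("train", "validation")

TOTAL_AREA_PER_PEAK = 1_000_000.0


class PeakTableError(ValueError):
    """Raised for malformed peak tables or profiles."""


class TransformKind(str, enum.Enum):
    """Per-peak variance-stabilizing transformation applied before row normalization."""

    none = "none"
    fourth_root = "fourth_root"
    log1p = "log1p"


@dataclass(frozen=True)
class Compound:
    """One target compound: name, relative retention time and diagnostic ions."""

    name: str
    rrt: float
    target_ion: int
    qualifier_ions: tuple[int, ...]
    full_name: str = ""

    def __post_init__(self) -> None:
        if self.rrt <= 0:
            raise ValueError(f"RRT must be positive for {self.name!r}, got {self.rrt}")
        if self.target_ion in self.qualifier_ions:
            raise ValueError(
                f"target ion {self.target_ion} of {self.name!r} duplicated in qualifiers"
            )


@dataclass(frozen=True)
class CompoundTable:
    """Ordered list of target compounds plus the internal standard.

    The entry order (ascending relative retention time) is the canonical
    compound order used throughout the package: CSV columns are remapped to
    it and ratio features are named from it.
    """

    entries: tuple[Compound, ...]
    internal_standard: str

    def __post_init__(self) -> None:
        names = [c.name for c in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique")

    @property
    def names(self) -> list[str]:
        """Target compound names, internal standard excluded."""
        return [c.name for c in self.entries if c.name != self.internal_standard]


def default_compound_table() -> CompoundTable:
    """The bundled cocaine-alkaloid target list (8 alkaloids + nonadecane IS)."""
    path = resources.files("ratiolink").joinpath("data/compounds.csv")
    entries = []
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                Compound(
                    name=row["name"],
                    rrt=float(row["rrt"]),
                    target_ion=int(row["target_ion"]),
                    qualifier_ions=tuple(int(q) for q in row["qualifier_ions"].split(";")),
                    full_name=row["full_name"],
                )
            )
    return CompoundTable(entries=tuple(entries), internal_standard="Nonadecane")


@dataclass(frozen=True)
class PeakProfile:
    """One sample's named peak-area vector plus identity metadata.

    ``group_id == SINGLE`` marks a specimen presumed unrelated to all batches.
    """

    sample_id: str
    group_id: str
    split: str
    peaks: pd.Series  # index = compound names, values = non-negative areas

    def __post_init__(self) -> None:
        values = self.peaks.to_numpy(dtype=float)
        if (values < 0).any():
            bad = self.peaks.index[values < 0][0]
            raise PeakTableError(
                f"negative peak area for sample {self.sample_id!r}, compound {bad!r}"
            )
        if self.split not in _SPLITS:
            raise PeakTableError(
                f"unknown split {self.split!r} for sample {self.sample_id!r}; "
                f"expected one of {_SPLITS}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.peaks.to_numpy(dtype=float)

    @property
    def compounds(self) -> list[str]:
        return list(self.peaks.index)

    def with_values(self, values: np.ndarray) -> "PeakProfile":
        return replace(self, peaks=pd.Series(values, index=self.peaks.index, dtype=float))


@dataclass(frozen=True)
class ProfileSet:
    """A collection of profiles over a common compound list.

    ``peaks`` is indexed by sample_id with one column per compound in
    canonical order; ``meta`` carries ``group_id`` and ``split`` per sample.
    ``noise_compounds`` names columns that were injected as resampled noise.
    ``transform`` records the preprocessing applied (None = raw).
    """

    peaks: pd.DataFrame
    meta: pd.DataFrame
    noise_compounds: tuple[str, ...] = ()
    transform: TransformKind | None = None

    def __post_init__(self) -> None:
        if self.peaks.index.has_duplicates:
            dup = self.peaks.index[self.peaks.index.duplicated()][0]
            raise PeakTableError(f"duplicate sample_id {dup!r}")
        if not self.peaks.index.equals(self.meta.index):
            raise PeakTableError("peaks and meta must share the same sample index")
        if (self.peaks.to_numpy() < 0).any():
            arr = self.peaks.to_numpy()
            i, j = np.argwhere(arr < 0)[0]
            raise PeakTableError(
                f"negative peak area for sample {self.peaks.index[i]!r}, "
                f"compound {self.peaks.columns[j]!r}"
            )
        unknown = set(self.meta["split"]) - set(_SPLITS)
        if unknown:
            raise PeakTableError(f"unknown split value(s): {sorted(unknown)}")
        overlap = set(self.noise_compounds) - set(self.peaks.columns)
        if overlap:
            raise PeakTableError(f"noise compounds not in table: {sorted(overlap)}")

    @property
    def compounds(self) -> list[str]:
        return list(self.peaks.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.peaks.index)

    @property
    def n_profiles(self) -> int:
        return len(self.peaks)

    @property
    def alkaloid_compounds(self) -> list[str]:
        """Original (non-noise) compounds."""
        return [c for c in self.peaks.columns if c not in self.noise_compounds]

    def profile(self, sample_id: str) -> PeakProfile:
        row = self.meta.loc[sample_id]
        return PeakProfile(
            sample_id=sample_id,
            group_id=row["group_id"],
            split=row["split"],
            peaks=self.peaks.loc[sample_id].astype(float),
        )

    def __iter__(self) -> Iterator[PeakProfile]:
        for sid in self.peaks.index:
            yield self.profile(sid)

    def subset(self, split: str) -> "ProfileSet":
        if split not in _SPLITS:
            raise PeakTableError(f"unknown split {split!r}")
        mask = self.meta["split"] == split
        return replace(self, peaks=self.peaks.loc[mask], meta=self.meta.loc[mask])


def read_peak_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    compound_table: CompoundTable | None = None,
) -> ProfileSet:
    """Read a peak-table CSV into a :class:`ProfileSet`.

    The CSV has a ``sample_id`` column, optional ``group_id`` and ``split``
    columns, and one numeric column per compound.  Metadata may instead live
    in a second CSV keyed by ``sample_id``.  An empty or missing group marks
    the sample as :data:`SINGLE`; a missing split defaults to ``train``.
    Columns are remapped to the compound table's canonical order when one is
    given.  Columns named ``noise_*`` are flagged as injected noise.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise PeakTableError(f"{path}: missing required 'sample_id' column")
    df = df.set_index("sample_id")

    if metadata_path is not None:
        meta_df = pd.read_csv(metadata_path, dtype={"sample_id": str}).set_index("sample_id")
        missing = set(df.index) - set(meta_df.index)
        if missing:
            raise PeakTableError(f"metadata missing sample(s): {sorted(missing)[:5]}")
        meta_df = meta_df.reindex(df.index)
    else:
        meta_cols = [c for c in ("group_id", "split") if c in df.columns]
        meta_df = df[meta_cols].copy()
        df = df.drop(columns=meta_cols)

    group = meta_df["group_id"] if "group_id" in meta_df.columns else pd.Series("", index=df.index)
    group = group.fillna("").astype(str).replace("", SINGLE)
    split = meta_df["split"] if "split" in meta_df.columns else pd.Series("train", index=df.index)
    split = split.fillna("train").astype(str)
    meta = pd.DataFrame({"group_id": group, "split": split}, index=df.index)

    peak_cols = [c for c in df.columns if c not in ("group_id", "split")]
    if len(peak_cols) < 2:
        raise PeakTableError(f"{path}: need at least 2 compound columns, found {len(peak_cols)}")
    try:
        peaks = df[peak_cols].astype(float)
    except ValueError as exc:
        raise PeakTableError(f"{path}: non-numeric peak value ({exc})") from exc
    if peaks.isna().any().any():
        sid = peaks.index[peaks.isna().any(axis=1)][0]
        raise PeakTableError(f"{path}: missing peak value for sample {sid!r}")

    noise_cols = tuple(c for c in peak_cols if c.startswith("noise_"))
    if compound_table is not None:
        canonical = compound_table.names
        missing = set(canonical) - set(peak_cols)
        if missing:
            raise PeakTableError(f"{path}: compound column(s) missing: {sorted(missing)}")
        ordered = canonical + [c for c in peak_cols if c not in canonical]
        peaks = peaks[ordered]

    return ProfileSet(peaks=peaks, meta=meta, noise_compounds=noise_cols)


def write_peak_table(pset: ProfileSet, path: str | Path) -> None:
    """Write a :class:`ProfileSet` to the package's peak-table CSV dialect."""
    out = pset.meta.copy()
    out["group_id"] = out["group_id"].replace(SINGLE, "")
    out = pd.concat([out, pset.peaks], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# preprocessing steps


def scale_to_total(p: PeakProfile, n_peaks: int | None = None) -> PeakProfile:
    """Scale a profile so its peaks sum to ``1e6 * n_peaks``.

    Proportions between peaks are unchanged; an all-zero profile is rejected.
    """
    values = p.values
    total = values.sum()
    if total <= 0:
        raise PeakTableError(f"all-zero profile {p.sample_id!r} cannot be scaled")
    if n_peaks is None:
        n_peaks = len(values)
    return p.with_values(values * (TOTAL_AREA_PER_PEAK * n_peaks / total))


def transform_profile(p: PeakProfile, t: TransformKind) -> PeakProfile:
    """Apply the chosen per-peak transformation (identity, x**0.25 or ln(1+x))."""
    t = TransformKind(t)
    if t is TransformKind.none:
        return p
    if t is TransformKind.fourth_root:
        return p.with_values(np.power(p.values, 0.25))
    return p.with_values(np.log1p(p.values))


def row_normalize(p: PeakProfile) -> PeakProfile:
    """Divide every peak by the row sum so the profile sums to one."""
    values = p.values
    total = values.sum()
    if total <= 0:
        raise PeakTableError(f"all-zero profile {p.sample_id!r} cannot be normalized")
    return p.with_values(values / total)


def _transform_frame(frame: pd.DataFrame, t: TransformKind) -> pd.DataFrame:
    t = TransformKind(t)
    if t is TransformKind.none:
        return frame
    if t is TransformKind.fourth_root:
        return frame.pow(0.25)
    return np.log1p(frame)


def preprocess(pset: ProfileSet, t: TransformKind = TransformKind.none) -> ProfileSet:
    """Scale to common total, transform, then row-normalize every profile.

    The applied transform is recorded in the returned set's provenance.
    Vectorized equivalent of chaining :func:`scale_to_total`,
    :func:`transform_profile` and :func:`row_normalize` per profile.
    """
    t = TransformKind(t)
    totals = pset.peaks.sum(axis=1)
    if (totals <= 0).any():
        sid = totals.index[totals <= 0][0]
        raise PeakTableError(f"all-zero profile {sid!r} cannot be preprocessed")
    n_peaks = pset.peaks.shape[1]
    scaled = pset.peaks.mul(TOTAL_AREA_PER_PEAK * n_peaks / totals, axis=0)
    transformed = _transform_frame(scaled, t)
    normalized = transformed.div(transformed.sum(axis=1), axis=0)
    return replace(pset, peaks=normalized, transform=t)
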