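"""Synthetic grouped GC-MS-like profile generator with known linkage.

Emulates the structure of a forensic alkaloid-profiling dataset: a number
of production batches (groups), each contributing several specimens, plus
"single" specimens presumed unrelated to every batch, split into training
and validation sets.  The default shape mirrors the study design this
package targets: 29 training groups / 280 grouped samples + 124 singles,
and 10 validation groups / 68 samples, 8 target compounds per profile.

Generative model per sample:

    peaks = base_composition * lognormal_noise * decay * total_area

* each batch (and each single) draws a base composition from a Dirichlet;
* within-batch variation is multiplicative lognormal noise per peak, with
  a configurable coefficient of variation -- multiplicative so peaks stay
  positive and linked samples stay approximately proportional;
* optionally, a subset of "unstable" compounds decays as
  ``(1 - rate)^months`` with a per-sample storage time, mimicking compound
  degradation during storage;
* a random total area models injection amount / instrument response.

In the noise-free limit (cv = 0, no degradation) members of a group are
exact positive rescalings of each other, so all their ratio differences
are identically zero -- a useful oracle for the feature code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ratiolink.pairing import ProfilePair, enumerate_pairs
from ratiolink.profiles import SINGLE, ProfileSet


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and noise parameters of the generated dataset.

    Defaults reproduce the target study shape (groups/samples/singles) with
    moderate within-batch variation and no compound instability.
    """

    n_train_groups: int = 29
    n_train_group_samples_total: int = 280
    n_singles: int = 124
    n_valid_groups: int = 10
    n_valid_samples_total: int = 68
    n_compounds: int = 8
    #: Dirichlet concentration for batch base compositions; scalar = symmetric.
    batch_concentration: float | tuple[float, ...] = 1.5
    #: coefficient of variation of the multiplicative lognormal peak noise
    within_group_cv: float = 0.10
    #: indices of compounds subject to storage degradation
    unstable_compounds: tuple[int, ...] = ()
    #: per-month fractional decay of unstable compounds, in [0, 1)
    degradation_rate: float = 0.0
    #: per-sample storage time drawn uniformly from this interval (months)
    storage_months_range: tuple[float, float] = (0.0, 15.0)
    #: raw total peak area drawn log-uniformly from this interval
    total_area_range: tuple[float, float] = (1e6, 5e7)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_train_groups",
            "n_train_group_samples_total",
            "n_singles",
            "n_valid_groups",
            "n_valid_samples_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_compounds < 2:
            raise ValueError("need at least 2 compounds")
        if not 0 <= self.degradation_rate < 1:
            raise ValueError("degradation_rate must be in [0, 1)")
        if self.within_group_cv < 0:
            raise ValueError("within_group_cv must be >= 0")
        if any(i < 0 or i >= self.n_compounds for i in self.unstable_compounds):
            raise ValueError("unstable compound index out of range")

    @property
    def alpha(self) -> np.ndarray:
        a = np.asarray(self.batch_concentration, dtype=float)
        if a.ndim == 0:
            a = np.full(self.n_compounds, float(a))
        if a.shape != (self.n_compounds,):
            raise ValueError("batch_concentration must be scalar or length n_compounds")
        return a


def _partition_group_sizes(total: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Random group sizes summing to ``total`` with every group >= 2."""
    if n_groups == 0:
        if total:
            raise ValueError("grouped samples requested but zero groups")
        return np.zeros(0, dtype=int)
    if total < 2 * n_groups:
        raise ValueError(
            f"cannot place {total} samples into {n_groups} groups of >= 2 members"
        )
    extra = rng.multinomial(total - 2 * n_groups, np.full(n_groups, 1.0 / n_groups))
    return extra + 2


def _lognormal_sigma(cv: float) -> float:
    # CV of a lognormal: sqrt(exp(sigma^2) - 1)
    return float(np.sqrt(np.log1p(cv**2)))


def generate(config: SyntheticConfig) -> ProfileSet:
    """Generate a :class:`ProfileSet` with known linkage; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    alpha = config.alpha
    sigma = _lognormal_sigma(config.within_group_cv)
    decay_base = 1.0 - config.degradation_rate
    lo_m, hi_m = config.storage_months_range
    log_lo, log_hi = np.log(config.total_area_range[0]), np.log(config.total_area_range[1])

    compounds = [f"C{i+1}" for i in range(config.n_compounds)]
    unstable = np.zeros(config.n_compounds, dtype=bool)
    unstable[list(config.unstable_compounds)] = True

    rows, sample_ids, group_ids, splits = [], [], [], []

    def _emit(base: np.ndarray, sid: str, gid: str, split: str) -> None:
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=config.n_compounds)
        months = rng.uniform(lo_m, hi_m)
        decay = np.where(unstable, decay_base**months, 1.0)
        area = np.exp(rng.uniform(log_lo, log_hi))
        profile = base * noise * decay
        rows.append(profile / profile.sum() * area)
        sample_ids.append(sid)
        group_ids.append(gid)
        splits.append(split)

    for split, n_groups, n_total, prefix in (
        ("train", config.n_train_groups, config.n_train_group_samples_total, "T"),
        ("validation", config.n_valid_groups, config.n_valid_samples_total, "V"),
    ):
        sizes = _partition_group_sizes(n_total, n_groups, rng)
        for g, size in enumerate(sizes, start=1):
            base = rng.dirichlet(alpha)
            for m in range(1, size + 1):
                _emit(base, f"{prefix}{g:03d}_{m:03d}", f"{prefix}G{g:03d}", split)

    for s in range(1, config.n_singles + 1):
        base = rng.dirichlet(alpha)
        _emit(base, f"S{s:03d}", SINGLE, "train")

    peaks = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"), columns=compounds)
    meta = pd.DataFrame(
        {"group_id": group_ids, "split": splits},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ProfileSet(peaks=peaks, meta=meta)


def truth_table(pset: ProfileSet) -> list[ProfilePair]:
    """Ground-truth labeled pairs for a generated set (both splits, concatenated)."""
    pairs: list[ProfilePair] = []
    for split in ("train", "validation"):
        if (pset.meta["split"] == split).sum() >= 2:
            pairs.extend(enumerate_pairs(pset, split))
    return pairs
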