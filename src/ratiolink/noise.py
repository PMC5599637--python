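"""Injection of artificial unstable peaks into a profile set.

Simulates extremely unstable compounds by appending extra peak columns
whose values are resampled uniformly, with replacement, from the pool of
existing peak values in the set.  Injected values therefore follow the
empirical distribution of the real peaks but carry no correlation with any
sample or compound.  Injection happens on raw areas, before preprocessing,
so the noise enters the row-normalization denominator and contaminates
every normalized peak -- while pairwise ratios between two original
compounds are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ratiolink.profiles import PeakTableError, ProfileSet

NOISE_PREFIX = "noise_"


@dataclass(frozen=True)
class NoiseSpec:
    """How many noise peaks to inject and from which value pool.

    ``pool_source="raw"`` draws from the set's peak values as given;
    ``"preprocessed"`` draws from row-normalized proportions instead.
    """

    n_noise_peaks: int = 4
    seed: int = 0
    pool_source: str = "raw"

    def __post_init__(self) -> None:
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")
        if self.pool_source not in ("raw", "preprocessed"):
            raise ValueError(f"unknown pool_source {self.pool_source!r}")


def add_noise_peaks(pset: ProfileSet, spec: NoiseSpec) -> ProfileSet:
    """Append ``spec.n_noise_peaks`` resampled noise columns to every profile.

    Each new cell is an i.i.d. draw from the pool of all existing peak
    values across all samples and compounds.  Deterministic given
    ``spec.seed``.  With 8 original peaks and 4 noise peaks the result has
    12 peaks (2/3 real data, 1/3 noise).
    """
    if pset.n_profiles == 0 or pset.peaks.shape[1] == 0:
        raise PeakTableError("cannot inject noise into an empty profile set")
    if spec.n_noise_peaks == 0:
        return pset

    pool = pset.peaks.to_numpy(dtype=float)
    if spec.pool_source == "preprocessed":
        pool = pool / pool.sum(axis=1, keepdims=True)
    pool = pool.ravel()

    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(pool, size=(pset.n_profiles, spec.n_noise_peaks), replace=True)

    existing = set(pset.peaks.columns)
    names = []
    i = 1
    while len(names) < spec.n_noise_peaks:
        name = f"{NOISE_PREFIX}{i}"
        if name not in existing:
            names.append(name)
        i += 1

    noise_df = pd.DataFrame(draws, index=pset.peaks.index, columns=names)
    return replace(
        pset,
        peaks=pd.concat([pset.peaks, noise_df], axis=1),
        noise_compounds=pset.noise_compounds + tuple(names),
    )
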