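"""Enumeration and labeling of profile pairs.

Ground-truth linkage comes from batch (group) membership: two profiles
from the same group are *linked*; a pair spanning two groups, or one group
and one "single" (a specimen presumed unrelated to every group), is
*unlinked*; a pair of two singles carries no usable truth and is discarded.
Train and validation splits never mix within a pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from ratiolink.profiles import SINGLE, PeakTableError, ProfileSet

LINKED = "linked"
UNLINKED = "unlinked"


@dataclass(frozen=True)
class ProfilePair:
    """An unordered sample pair with its linkage label and split."""

    sample_1: str
    sample_2: str
    label: str
    split: str

    def __post_init__(self) -> None:
        if self.sample_1 >= self.sample_2:
            raise ValueError(
                f"pair must be ordered sample_1 < sample_2, got "
                f"({self.sample_1!r}, {self.sample_2!r})"
            )


def enumerate_pairs(pset: ProfileSet, split: str) -> list[ProfilePair]:
    """All labeled unordered pairs within one split; single-single pairs dropped."""
    meta = pset.meta[pset.meta["split"] == split]
    if len(meta) < 2:
        raise PeakTableError(f"need at least 2 profiles in split {split!r}, found {len(meta)}")
    sids = sorted(meta.index)
    groups = meta["group_id"]
    pairs = []
    for s1, s2 in combinations(sids, 2):
        g1, g2 = groups[s1], groups[s2]
        if g1 == SINGLE and g2 == SINGLE:
            continue
        label = LINKED if (g1 == g2 and g1 != SINGLE) else UNLINKED
        pairs.append(ProfilePair(s1, s2, label, split))
    return pairs


def pair_counts(pairs: Sequence[ProfilePair]) -> tuple[int, int]:
    """(n_linked, n_unlinked) over a pair list (discarded pairs never appear)."""
    n_linked = sum(1 for p in pairs if p.label == LINKED)
    return n_linked, len(pairs) - n_linked
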