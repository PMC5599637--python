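import numpy as np
import pandas as pd
import pytest

import ratiolink as rl
from ratiolink.profiles import PeakProfile, ProfileSet


def make_profile(values, sample_id="s1", group_id="g1", split="train", compounds=None):
    values = np.asarray(values, dtype=float)
    if compounds is None:
        compounds = [f"C{i+1}" for i in range(len(values))]
    return PeakProfile(
        sample_id=sample_id,
        group_id=group_id,
        split=split,
        peaks=pd.Series(values, index=compounds),
    )


def make_set(rows, group_ids, splits=None, compounds=None, noise=()):
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    sids = [f"s{i+1:02d}" for i in range(n)]
    if compounds is None:
        compounds = [f"C{i+1}" for i in range(rows.shape[1])]
    if splits is None:
        splits = ["train"] * n
    peaks = pd.DataFrame(rows, index=pd.Index(sids, name="sample_id"), columns=compounds)
    meta = pd.DataFrame(
        {"group_id": group_ids, "split": splits}, index=pd.Index(sids, name="sample_id")
    )
    return ProfileSet(peaks=peaks, meta=meta, noise_compounds=tuple(noise))


@pytest.fixture
def small_set():
    """Two 2-member groups plus two singles, 4 compounds, all train."""
    rng = np.random.default_rng(42)
    rows = rng.uniform(1e4, 1e6, size=(6, 4))
    rows[1] = rows[0] * 3.0  # s02 proportional to s01 (same batch, scaled)
    return make_set(
        rows, ["A", "A", "B", "B", rl.SINGLE, rl.SINGLE]
    )


@pytest.fixture(scope="session")
def tiny_synthetic():
    """Small generated dataset reused by slower tests (deterministic)."""
    cfg = rl.SyntheticConfig(
        n_train_groups=5,
        n_train_group_samples_total=20,
        n_singles=8,
        n_valid_groups=3,
        n_valid_samples_total=10,
        seed=123,
    )
    return rl.generate(cfg)
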