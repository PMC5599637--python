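"""Pair-comparison features: ratios, Pearson distance, peak/ratio differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ratiolink as rl
from ratiolink.features import (
    build_feature_matrix,
    n_ratios,
    pairwise_ratios,
    peak_differences,
    pearson_distance,
    ratio_differences,
    ratio_involves_noise,
    ratio_pair_names,
)
from ratiolink.profiles import PeakTableError
from tests.conftest import make_profile, make_set

positive_peaks = st.lists(
    st.floats(min_value=1e-3, max_value=1e9), min_size=3, max_size=12
)


class TestNRatios:
    @pytest.mark.parametrize("n,expected", [(2, 1), (8, 28), (12, 66)])
    def test_counts(self, n, expected):
        assert n_ratios(n) == expected

    def test_rejects_small_n(self):
        with pytest.raises(ValueError):
            n_ratios(1)

    def test_matches_enumeration(self):
        for k in range(2, 13):
            names = [f"C{i}" for i in range(k)]
            assert n_ratios(k) == len(ratio_pair_names(names))


class TestPairwiseRatios:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0.0, 5.0, 0.0), (5.0, 0.0, 1.0), (0.0, 0.0, 0.0), (500.0, 1500.0, 0.25)],
    )
    def test_endpoints_and_arithmetic(self, a, b, expected):
        r = pairwise_ratios(make_profile([a, b]))
        assert r["C1+C2"] == expected

    def test_numerator_is_earlier_compound(self):
        r = pairwise_ratios(make_profile([1.0, 3.0, 4.0]))
        assert r["C1+C2"] == pytest.approx(0.25)
        assert r["C1+C3"] == pytest.approx(0.2)
        assert r["C2+C3"] == pytest.approx(3 / 7)

    @settings(max_examples=50, deadline=None)
    @given(values=positive_peaks, scalar=st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariant(self, values, scalar):
        p = make_profile(values)
        q = p.with_values(p.values * scalar)
        np.testing.assert_allclose(
            pairwise_ratios(p).to_numpy(), pairwise_ratios(q).to_numpy(), rtol=1e-9
        )

    @settings(max_examples=30, deadline=None)
    @given(values=positive_peaks)
    def test_complement_sums_to_one(self, values):
        """a/(a+b) + b/(b+a) = 1; only the canonical orientation is stored."""
        p = make_profile(values)
        r = pairwise_ratios(p).to_numpy()
        rev = p.with_values(p.values[::-1])
        r_rev = pairwise_ratios(rev).to_numpy()
        # reversing compound order flips every ratio to its complement
        # (1 - r loses relative precision for ratios near 1, hence the atol)
        np.testing.assert_allclose(np.sort(r), np.sort(1 - r_rev), rtol=1e-6, atol=1e-9)


class TestPearsonDistance:
    def test_identical_profiles_zero(self):
        p = make_profile([1.0, 5.0, 2.0, 8.0])
        assert pearson_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_is_one(self):
        p1 = make_profile([1.0, 2.0, 3.0])
        p2 = make_profile([3.0, 2.0, 1.0], sample_id="s2")
        assert pearson_distance(p1, p2) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        p1 = make_profile([2.0, 2.0, 2.0])
        p2 = make_profile([1.0, 2.0, 3.0], sample_id="s2")
        with pytest.raises(PeakTableError, match="variance"):
            pearson_distance(p1, p2)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p1 = make_profile(rng.uniform(0, 1, 8))
            p2 = make_profile(rng.uniform(0, 1, 8), sample_id="s2")
            d = pearson_distance(p1, p2)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(pearson_distance(p2, p1), rel=1e-12)


class TestPeakDifferences:
    def test_identical_profiles_all_zero(self):
        p = make_profile([0.1, 0.4, 0.5])
        np.testing.assert_array_equal(peak_differences(p, p).values.to_numpy(), 0.0)

    @pytest.mark.parametrize(
        "x1,x2,expected", [(100.0, 300.0, 0.5), (0.0, 5.0, 1.0), (0.0, 0.0, 0.0)]
    )
    def test_pointwise(self, x1, x2, expected):
        v = peak_differences(
            make_profile([x1, 1.0]), make_profile([x2, 1.0], sample_id="s2")
        ).values
        assert v.iloc[0] == expected

    def test_symmetric(self):
        p1 = make_profile([1.0, 2.0, 3.0])
        p2 = make_profile([4.0, 0.5, 3.0], sample_id="s2")
        np.testing.assert_allclose(
            peak_differences(p1, p2).values, peak_differences(p2, p1).values
        )


class TestRatioDifferences:
    def test_identical_profiles_all_zero(self):
        p = make_profile([1.0, 2.0, 3.0, 4.0])
        assert (ratio_differences(p, p).values == 0).all()

    def test_lengths(self):
        for k, m in [(8, 28), (12, 66)]:
            p1 = make_profile(np.arange(1, k + 1, dtype=float))
            p2 = make_profile(np.arange(2, k + 2, dtype=float), sample_id="s2")
            assert len(ratio_differences(p1, p2).values) == m

    def test_single_coordinate_arithmetic(self):
        p1 = make_profile([1.0, 3.0])  # ratio 0.25
        p2 = make_profile([3.0, 1.0], sample_id="s2")  # ratio 0.75
        assert ratio_differences(p1, p2).values.iloc[0] == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None)
    @given(
        values1=positive_peaks,
        c1=st.floats(min_value=1e-6, max_value=1e6),
        c2=st.floats(min_value=1e-6, max_value=1e6),
        seed=st.integers(0, 2**16),
    )
    def test_normalization_free(self, values1, c1, c2, seed):
        """rd(p1, p2) = rd(c1*p1, c2*p2) for any positive scalars: the core claim."""
        rng = np.random.default_rng(seed)
        p1 = make_profile(values1)
        p2 = make_profile(rng.uniform(1e-3, 1e6, len(values1)), sample_id="s2")
        base = ratio_differences(p1, p2).values.to_numpy()
        scaled = ratio_differences(
            p1.with_values(p1.values * c1), p2.with_values(p2.values * c2)
        ).values.to_numpy()
        np.testing.assert_allclose(base, scaled, rtol=0, atol=1e-12)
        assert ((base >= 0) & (base <= 1)).all()


class TestNoiseInvolvement:
    def test_38_of_66_touch_noise(self):
        compounds = [f"A{i}" for i in range(8)] + [f"noise_{i}" for i in range(1, 5)]
        mask = ratio_involves_noise(compounds, [c for c in compounds if "noise" in c])
        assert len(mask) == 66
        assert int(mask.sum()) == 38
        assert int((~mask).sum()) == 28

    def test_matches_brute_force(self):
        compounds = ["a", "b", "c", "noise_1", "noise_2"]
        noise = {"noise_1", "noise_2"}
        expected = [
            (x in noise or y in noise) for x, y in ratio_pair_names(compounds)
        ]
        np.testing.assert_array_equal(ratio_involves_noise(compounds, noise), expected)


class TestBuildFeatureMatrix:
    @pytest.fixture()
    def pairs_and_set(self, small_set):
        return small_set, rl.enumerate_pairs(small_set, "train")

    def test_matches_single_pair_ops(self, pairs_and_set):
        pset, pairs = pairs_and_set
        pp = rl.preprocess(pset)
        for method, op in [
            ("peak_diff", peak_differences),
            ("ratio_diff", ratio_differences),
        ]:
            fm = build_feature_matrix(pp, pairs, method)
            for i, pair in enumerate(pairs):
                expected = op(pp.profile(pair.sample_1), pp.profile(pair.sample_2))
                np.testing.assert_allclose(
                    fm.X.iloc[i].to_numpy(), expected.values.to_numpy(), rtol=1e-12
                )
        fm = build_feature_matrix(pp, pairs, "pearson")
        for i, pair in enumerate(pairs):
            expected = pearson_distance(pp.profile(pair.sample_1), pp.profile(pair.sample_2))
            assert fm.X.iloc[i, 0] == pytest.approx(expected, rel=1e-12)

    def test_labels_align_with_pairs(self, pairs_and_set):
        pset, pairs = pairs_and_set
        fm = build_feature_matrix(pset, pairs, "ratio_diff")
        assert list(fm.labels) == [p.label for p in pairs]

    def test_csv_roundtrip(self, tmp_path, pairs_and_set):
        from ratiolink.features import read_feature_matrix

        pset, pairs = pairs_and_set
        fm = build_feature_matrix(pset, pairs, "ratio_diff")
        fm.to_csv(tmp_path / "fm.csv")
        back = read_feature_matrix(tmp_path / "fm.csv", "ratio_diff")
        np.testing.assert_allclose(back.X.to_numpy(), fm.X.to_numpy())
        assert back.feature_names == fm.feature_names

    def test_unknown_method_rejected(self, pairs_and_set):
        pset, pairs = pairs_and_set
        with pytest.raises(ValueError, match="unknown feature method"):
            build_feature_matrix(pset, pairs, "cosine")
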