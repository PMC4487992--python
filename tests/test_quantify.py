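"""Count matrix assembly, detection thresholds and median-of-ratios
normalization, cross-checked against an independent implementation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from srnaqc import (
    build_count_matrix,
    detected_features,
    normalize,
    size_factors,
)
from srnaqc.io_formats import CountMatrix


def matrix_from(data, classes=None):
    df = pd.DataFrame(data)
    cls = pd.Series({f: (classes or {}).get(f, "miRNA") for f in df.index})
    return CountMatrix(counts=df.astype(float), classes=cls)


class TestBuildCountMatrix:
    def test_single_library_round_trips_vector(self):
        m = build_count_matrix({"lib1": {"a": 3, "b": 7}}, {"a": "miRNA", "b": "repeat"})
        assert m.counts["lib1"].to_dict() == {"a": 3.0, "b": 7.0}

    def test_disjoint_features_zero_filled(self):
        m = build_count_matrix(
            {"l1": {"a": 5}, "l2": {"b": 2}}, {"a": "miRNA", "b": "miRNA"}
        )
        assert m.counts.loc["a", "l2"] == 0.0
        assert m.counts.loc["b", "l1"] == 0.0

    def test_column_sums_match_inputs(self):
        rng = np.random.default_rng(3)
        per_lib = {
            f"l{j}": {f"f{i}": int(c) for i, c in enumerate(rng.integers(0, 50, 20))}
            for j in range(4)
        }
        classes = {f"f{i}": "miRNA" for i in range(20)}
        m = build_count_matrix(per_lib, classes)
        for lib, counts in per_lib.items():
            assert m.counts[lib].sum() == sum(counts.values())

    def test_duplicate_library_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_count_matrix(
                [("l1", {"a": 1}), ("l1", {"a": 2})], {"a": "miRNA"}
            )


class TestDetectedFeatures:
    def test_threshold_one_single_library(self):
        m = matrix_from({"l1": {"A": 5.0, "B": 0.0}})
        assert detected_features(m, 1) == {"A"}

    def test_three_library_toy_matches_brute_force(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            rng.integers(0, 30, size=(25, 3)).astype(float),
            index=[f"f{i}" for i in range(25)],
            columns=["l1", "l2", "l3"],
        )
        m = matrix_from(df)
        expected = {f for f in df.index if all(df.loc[f, c] >= 10 for c in df.columns)}
        assert detected_features(m, 10) == expected

    def test_any_library_scope(self):
        m = matrix_from({"l1": {"A": 5.0, "B": 0.0}, "l2": {"A": 0.0, "B": 3.0}})
        assert detected_features(m, 1, scope="any_library") == {"A", "B"}
        assert detected_features(m, 1) == set()

    def test_threshold_below_one_rejected(self):
        m = matrix_from({"l1": {"A": 5.0}})
        with pytest.raises(ValueError):
            detected_features(m, 0)

    @given(
        st.lists(
            st.lists(st.integers(0, 40), min_size=3, max_size=3),
            min_size=1,
            max_size=12,
        )
    )
    def test_detected_sets_are_nested_across_thresholds(self, rows):
        df = pd.DataFrame(
            np.asarray(rows, dtype=float),
            index=[f"f{i}" for i in range(len(rows))],
            columns=["l1", "l2", "l3"],
        )
        m = matrix_from(df)
        s1, s10, s20 = (detected_features(m, t) for t in (1, 10, 20))
        assert s20 <= s10 <= s1


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        m = matrix_from({"l1": {"a": 5.0, "b": 9.0}, "l2": {"a": 5.0, "b": 9.0}})
        assert np.allclose(size_factors(m), [1.0, 1.0])

    def test_doubled_library_closed_form(self):
        m = matrix_from(
            {"l1": {"a": 10.0, "b": 20.0, "c": 40.0},
             "l2": {"a": 20.0, "b": 40.0, "c": 80.0}}
        )
        sf = size_factors(m)
        assert sf["l1"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert sf["l2"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            rng.integers(1, 200, size=(30, 3)).astype(float),
            index=[f"f{i}" for i in range(30)],
            columns=["l1", "l2", "l3"],
        )
        base = size_factors(matrix_from(df))
        scaled_df = df.copy()
        scaled_df["l2"] *= 5.0
        scaled = size_factors(matrix_from(scaled_df))
        # scaling one library by c multiplies its factor by c / c^(1/m) and
        # divides the others by c^(1/m) (the geometric-mean shift)
        shift = 5.0 ** (1 / 3)
        assert np.allclose(scaled["l2"], base["l2"] * 5.0 / shift)
        assert np.allclose(scaled["l1"], base["l1"] / shift)
        assert np.allclose(scaled["l3"], base["l3"] / shift)

    def test_no_common_feature_advises_pseudocount(self):
        m = matrix_from({"l1": {"a": 5.0, "b": 0.0}, "l2": {"a": 0.0, "b": 3.0}})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(m)
        assert (size_factors(m, pseudocount=0.5) > 0).all()

    def test_matches_independent_deseq_implementation(self):
        """Cross-check against pydeseq2's median-of-ratios fit."""
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(19)
        counts = rng.negative_binomial(5, 0.1, size=(6, 40))
        depth = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 3.0])[:, None]
        counts = np.rint(counts * depth).astype(int)
        samples = [f"s{i}" for i in range(6)]
        dds = DeseqDataSet(
            counts=pd.DataFrame(counts, index=samples),
            metadata=pd.DataFrame({"condition": ["a"] * 6}, index=samples),
            design="~1",
            quiet=True,
        )
        dds.fit_size_factors()
        oracle = np.asarray(dds.obs["size_factors"], dtype=float)
        # our factors fix the arbitrary overall scale at geometric mean 1;
        # compare on the same gauge
        oracle = oracle / np.exp(np.mean(np.log(oracle)))
        df = pd.DataFrame(
            counts.T.astype(float),
            index=[f"f{i}" for i in range(40)],
            columns=samples,
        )
        ours = size_factors(matrix_from(df)).to_numpy()
        assert np.allclose(ours, oracle, rtol=1e-6)


class TestNormalize:
    def test_unit_factors_are_identity(self):
        m = matrix_from({"l1": {"a": 5.0}, "l2": {"a": 7.0}})
        out = normalize(m, pd.Series({"l1": 1.0, "l2": 1.0}))
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_renormalization_is_idempotent(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            rng.integers(1, 500, size=(40, 4)).astype(float),
            index=[f"f{i}" for i in range(40)],
            columns=list("abcd"),
        )
        m = matrix_from(df)
        once = normalize(m, size_factors(m))
        again = normalize(once, size_factors(once))
        assert np.allclose(size_factors(once), 1.0, atol=1e-9)
        assert np.allclose(once.counts, again.counts, atol=1e-9)

    def test_scaling_then_normalizing_recovers_matrix(self):
        """Artificially inflating one library is undone by normalization.

        With a geometric-mean reference, scaling one of m libraries by c
        shifts every normalized entry by the same global c**(1/m) (the
        reference itself moves); the between-library structure is recovered
        exactly, so the recovery is checked up to that predicted constant.
        """
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            rng.integers(1, 300, size=(25, 3)).astype(float),
            index=[f"f{i}" for i in range(25)],
            columns=["l1", "l2", "l3"],
        )
        m = matrix_from(df)
        norm_base = normalize(m, size_factors(m)).counts
        scaled_df = df.copy()
        scaled_df["l3"] *= 7.0
        m_scaled = matrix_from(scaled_df)
        norm_scaled = normalize(m_scaled, size_factors(m_scaled)).counts
        shift = 7.0 ** (1 / 3)
        assert np.allclose(norm_base * shift, norm_scaled, rtol=1e-9)

    def test_nonpositive_factor_rejected(self):
        m = matrix_from({"l1": {"a": 5.0}, "l2": {"a": 7.0}})
        with pytest.raises(ValueError):
            normalize(m, pd.Series({"l1": 0.0, "l2": 1.0}))
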