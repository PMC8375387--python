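import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gsdiscrim import (
    ExpressionDataset,
    call_deregulated,
    estimate_fdr_permutation,
    fold_change,
    sam_statistics,
)
from conftest import make_dataset
from _oracles import pooled_t


def _two_group(rows, n1, n2, condition="b"):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    values = pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])],
                          columns=[f"s{i}" for i in range(n1 + n2)])
    groups = pd.Series(["a"] * n1 + ["b"] * n2, index=values.columns)
    return ExpressionDataset(values, groups=groups, condition=condition)


class TestSamStatistic:
    def test_hand_evaluated_three_vs_three(self):
        ds = _two_group([[1, 2, 3, 4, 5, 6]], 3, 3)
        d, s, _ = sam_statistics(ds, s0=0.0)
        assert s.iloc[0] == pytest.approx(math.sqrt(2 / 3), abs=1e-6)
        assert d.iloc[0] == pytest.approx(3.674235, abs=1e-5)

    def test_identical_groups_give_zero(self):
        ds = _two_group([[2, 3, 4, 2, 3, 4]], 3, 3)
        d, _, _ = sam_statistics(ds, s0=0.5)
        assert d.iloc[0] == 0.0

    def test_abs_d_non_increasing_in_s0(self, rng):
        ds = _two_group(rng.normal(size=(30, 8)), 4, 4)
        prev = None
        for s0 in [0.0, 0.1, 0.5, 2.0]:
            d, _, _ = sam_statistics(ds, s0=s0)
            if prev is not None:
                assert (np.abs(d.to_numpy()) <= prev + 1e-12).all()
            prev = np.abs(d.to_numpy())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_pooled_t_at_s0_zero(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 10))
        ds = _two_group(X, 5, 5)
        d, _, _ = sam_statistics(ds, s0=0.0)
        for i in range(40):
            expected = pooled_t(list(X[i, :5]), list(X[i, 5:]))
            assert d.iloc[i] == pytest.approx(expected, abs=1e-9)

    def test_small_group_rejected(self):
        ds = _two_group([[1, 2, 3]], 1, 2)
        with pytest.raises(ValueError, match="at least 2"):
            sam_statistics(ds, s0=0.0)


class TestPermutationFdr:
    def test_exhaustive_three_vs_three_enumerates_twenty(self, caplog):
        ds = _two_group(np.random.default_rng(0).normal(size=(50, 6)), 3, 3)
        d, _, s0 = sam_statistics(ds, s0=0.0)
        with caplog.at_level("INFO"):
            estimate_fdr_permutation(ds, d, s0, n_perm="exhaustive")
        assert any("20 label assignments" in r.message for r in caplog.records)

    def test_label_swap_leaves_q_and_fc_unchanged(self):
        rng = np.random.default_rng(1)
        ds = _two_group(rng.normal(size=(40, 6)), 3, 3, condition="b")
        ds_swapped = _two_group(ds.values.to_numpy(), 3, 3, condition="a")
        d1, _, _ = sam_statistics(ds, s0=0.1)
        d2, _, _ = sam_statistics(ds_swapped, s0=0.1)
        assert np.allclose(d1.to_numpy(), -d2.to_numpy())
        fc1, fc2 = fold_change(ds), fold_change(ds_swapped)
        assert np.allclose(fc1["fc"], fc2["fc"])
        assert np.allclose(fc1["mean_diff"], -fc2["mean_diff"])
        q1 = estimate_fdr_permutation(ds, d1, 0.1, n_perm="exhaustive")
        q2 = estimate_fdr_permutation(ds_swapped, d2, 0.1, n_perm="exhaustive")
        assert np.allclose(q1.to_numpy(), q2.to_numpy())

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(2)
        ds = _two_group(rng.normal(size=(100, 6)), 3, 3)
        d, _, _ = sam_statistics(ds, s0=0.0)
        q = estimate_fdr_permutation(ds, d, 0.0, n_perm="exhaustive")
        order = np.argsort(-np.abs(d.to_numpy()))
        assert (np.diff(q.to_numpy()[order]) >= -1e-12).all()

    def test_planted_gene_attains_minimum_q(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(501, 20))
        X[0, 10:] += 4.0
        ds = _two_group(X, 10, 10)
        d, _, s0 = sam_statistics(ds, s0="auto")
        q = estimate_fdr_permutation(ds, d, s0, n_perm=200, seed=1)
        assert q.iloc[0] == q.min()

    def test_zero_permutations_rejected(self, dataset):
        d, _, s0 = sam_statistics(dataset, s0=0.0)
        with pytest.raises(ValueError, match="positive"):
            estimate_fdr_permutation(dataset, d, s0, n_perm=0)


class TestFoldChangeAndCalls:
    def test_fold_change_direction_and_magnitude(self):
        ds = _two_group([[4.0, 4.0, 5.0, 5.0], [5.0, 5.0, 4.62, 4.62], [3.0, 3.0, 3.0, 3.0]], 2, 2)
        fc = fold_change(ds)
        assert fc.loc["g0", "fc"] == pytest.approx(2.0)
        assert fc.loc["g0", "mean_diff"] == pytest.approx(1.0)
        assert fc.loc["g1", "fc"] == pytest.approx(2 ** 0.38, abs=1e-5)
        assert fc.loc["g1", "mean_diff"] < 0
        assert fc.loc["g2", "fc"] == pytest.approx(1.0)

    @pytest.mark.parametrize("fc,q,mean_diff,expected", [
        (1.5, 0.005, 0.585, "up"),
        (1.2, 0.001, 0.263, "none"),       # FC gate fails
        (1 / 0.7, 0.004, math.log2(0.7), "down"),
        (1.5, 0.02, 0.585, "none"),        # FDR gate fails
    ])
    def test_joint_gates(self, fc, q, mean_diff, expected):
        table = pd.DataFrame(
            {"d": [np.sign(mean_diff)], "s": [1.0], "mean_diff": [mean_diff],
             "fc": [fc], "q": [q]},
            index=["gX"],
        )
        out, up, down = call_deregulated(table, 1.3, 0.01)
        assert out.loc["gX", "call"] == expected

    def test_lists_ordered_by_strength(self):
        table = pd.DataFrame(
            {"d": [1.0, 3.0, -2.0], "s": [1] * 3, "mean_diff": [0.6, 0.7, -0.8],
             "fc": [1.6, 1.7, 1.8], "q": [0.001] * 3},
            index=["a", "b", "c"],
        )
        _, up, down = call_deregulated(table, 1.3, 0.01)
        assert up == ["b", "a"] and down == ["c"]

    def test_threshold_domain_checked(self):
        table = pd.DataFrame({"d": [1.0], "s": [1.0], "mean_diff": [1.0], "fc": [2.0], "q": [0.001]})
        with pytest.raises(ValueError):
            call_deregulated(table, 0.9, 0.01)
        with pytest.raises(ValueError):
            call_deregulated(table, 1.3, 1.5)

    @given(st.integers(0, 10_000))
    def test_fc_is_two_to_abs_mean_diff(self, seed):
        rng = np.random.default_rng(seed)
        ds = _two_group(rng.normal(size=(5, 6)), 3, 3)
        fc = fold_change(ds)
        assert np.allclose(fc["fc"], 2.0 ** np.abs(fc["mean_diff"]))
        assert (fc["fc"] >= 1.0).all()
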