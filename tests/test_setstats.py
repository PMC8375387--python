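import numpy as np
import pandas as pd
import pytest

from gsdiscrim import (
    cluster_order,
    logfc_concordance,
    overlap_hypergeometric,
    set_group_test,
    upregulated_sets,
)
from gsdiscrim.faime import SetScoreMatrix
from _oracles import hypergeom_tail_exact


def _scores(matrix, n_ctrl, n_cond, set_names=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    names = set_names or [f"S{i}" for i in range(matrix.shape[0])]
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_cond)]
    df = pd.DataFrame(matrix, index=names, columns=samples)
    groups = pd.Series(["ctrl"] * n_ctrl + ["cond"] * n_cond, index=samples)
    return SetScoreMatrix(df, groups, "cond")


class TestSetGroupTest:
    def test_identical_distributions_give_zero_t(self):
        sm = _scores([[1, 2, 3, 1, 2, 3]], 3, 3)
        table = set_group_test(sm)
        assert table["t"].iloc[0] == pytest.approx(0.0)
        assert upregulated_sets(table) == []

    def test_large_shift_highly_significant(self, rng):
        ctrl = rng.normal(0, 1, size=(1, 9))
        cond = rng.normal(10, 1, size=(1, 8))
        sm = _scores(np.hstack([ctrl, cond]), 9, 8)
        table = set_group_test(sm)
        assert table["p"].iloc[0] < 1e-6
        assert table["direction"].iloc[0] > 0
        assert upregulated_sets(table) == ["S0"]

    def test_label_swap_negates_t(self, rng):
        X = rng.normal(size=(5, 10))
        a = set_group_test(_scores(X, 5, 5))
        sm = _scores(X, 5, 5)
        sm.condition = "ctrl"
        b = set_group_test(sm)
        assert np.allclose(a["t"], -b["t"])
        assert np.allclose(a["p"], b["p"])

    def test_zero_variance_set_excluded_with_warning(self, caplog, rng):
        X = np.vstack([np.ones(10), rng.normal(size=10)])
        with caplog.at_level("WARNING"):
            table = set_group_test(_scores(X, 5, 5))
        assert list(table.index) == ["S1"]


class TestOverlap:
    def test_hand_computed_tail(self):
        uni = [f"S{i}" for i in range(10)]
        res = overlap_hypergeometric(uni[:5], uni[:4], uni)
        assert res.overlap == 4
        assert res.p == pytest.approx(5 / 210, abs=1e-9)
        assert set(res.overlap_names) == set(uni[:4])

    def test_empty_overlap_gives_one(self):
        uni = [f"S{i}" for i in range(10)]
        res = overlap_hypergeometric(uni[:3], uni[5:8], uni)
        assert res.overlap == 0 and res.p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 20))
        uni = [f"S{i}" for i in range(N)]
        a = list(rng.choice(uni, size=rng.integers(1, N), replace=False))
        b = list(rng.choice(uni, size=rng.integers(1, N), replace=False))
        res = overlap_hypergeometric(a, b, uni)
        assert res.p == pytest.approx(
            hypergeom_tail_exact(N, len(a), len(b), res.overlap), abs=1e-12
        )

    def test_subset_violation_listed(self):
        with pytest.raises(ValueError, match="ROGUE"):
            overlap_hypergeometric(["ROGUE"], ["S0"], ["S0", "S1"])


class TestClusterOrder:
    def test_identical_columns_adjacent(self, rng):
        X = rng.normal(size=(6, 5))
        df = pd.DataFrame(np.hstack([X, X[:, [0]]]),
                          index=[f"r{i}" for i in range(6)],
                          columns=["a", "b", "c", "d", "e", "a2"])
        order = cluster_order(df, axis="columns")
        assert abs(order.index("a") - order.index("a2")) == 1

    def test_one_dimensional_merge_structure(self):
        # rows at 0, 1 and 10 (after z-scoring the pattern is preserved):
        # the two close rows must be adjacent leaves
        df = pd.DataFrame(
            [[0.0, 1.0, 2.0], [0.2, 1.2, 2.2], [10.0, 8.0, 6.0]],
            index=["near1", "near2", "far"], columns=list("abc"),
        )
        order = cluster_order(df, axis="rows")
        assert abs(order.index("near1") - order.index("near2")) == 1

    def test_permutation_invariant_partition(self, rng):
        X = rng.normal(size=(8, 6))
        df = pd.DataFrame(X, index=[f"r{i}" for i in range(8)], columns=list("abcdef"))
        perm = rng.permutation(8)
        order1 = cluster_order(df, axis="rows")
        order2 = cluster_order(df.iloc[perm], axis="rows")
        assert sorted(order1) == sorted(order2)

    def test_single_item_axis_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["r"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_order(df, axis="rows")


class TestConcordance:
    def _series(self, vals, prefix="g"):
        return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))], dtype=float)

    def test_identical_vectors(self):
        fc = self._series([0.5, -1.0, 2.0, 0.1])
        assert logfc_concordance(fc, fc.copy()).r == pytest.approx(1.0)

    def test_negated_vectors(self):
        fc = self._series([0.5, -1.0, 2.0, 0.1])
        assert logfc_concordance(fc, -fc).r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        x = self._series([1, 2, 3])
        y = self._series([2, 1, 3])
        res = logfc_concordance(x, y)
        assert res.r == pytest.approx(0.5, abs=1e-9)
        assert res.n_genes == 3

    def test_common_deregulated_requires_same_direction(self):
        fc = self._series([1.0, -1.0, 1.0, 1.0])
        calls_a = pd.Series(["up", "down", "up", "none"], index=fc.index)
        calls_b = pd.Series(["up", "down", "down", "up"], index=fc.index)
        res = logfc_concordance(fc, fc * 0.9 + self._series([0, 0.2, -0.1, 0.3]), calls_a, calls_b)
        assert set(res.common_deregulated) == {"g0", "g1"}

    def test_insufficient_or_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="3 shared"):
            logfc_concordance(self._series([1, 2]), self._series([1, 2]))
        flat = self._series([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="variance"):
            logfc_concordance(flat, self._series([1, 2, 3]))
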