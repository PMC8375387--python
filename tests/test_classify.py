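import numpy as np
import pandas as pd
import pytest

from gsdiscrim import pca_transform, pc_separation_test, resample_random_sets, roc_auc
from gsdiscrim.classify import _pair_auc
from gsdiscrim.faime import SetScoreMatrix
from _oracles import auc_pair_count


def _scores(matrix, n_ctrl, n_cond, set_names=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    names = set_names or [f"S{i}" for i in range(matrix.shape[0])]
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_cond)]
    df = pd.DataFrame(matrix, index=names, columns=samples)
    groups = pd.Series(["ctrl"] * n_ctrl + ["cond"] * n_cond, index=samples)
    return SetScoreMatrix(df, groups, "cond")


class TestPca:
    def test_collinear_samples_load_one_component(self, rng):
        t = rng.normal(size=8)
        X = np.vstack([2 * t, -1 * t])  # samples exactly on a line in set space
        res = pca_transform(_scores(X, 4, 4), standardize=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_components_orthonormal(self, rng):
        X = rng.normal(size=(6, 12))
        res = pca_transform(_scores(X, 6, 6))
        V = res.components.to_numpy()
        assert np.allclose(V @ V.T, np.eye(V.shape[0]), atol=1e-9)

    def test_exact_two_by_two_covariance(self, rng):
        # construct samples whose covariance is exactly [[2, 1], [1, 2]]:
        # eigenvalues (3, 1) -> explained variance fractions (0.75, 0.25)
        n = 40
        Z = rng.normal(size=(n, 2))
        Z -= Z.mean(0)
        # whiten exactly, then color with the Cholesky factor of the target
        C = np.linalg.cholesky(np.cov(Z, rowvar=False))
        W = Z @ np.linalg.inv(C).T
        target = np.array([[2.0, 1.0], [1.0, 2.0]])
        X = W @ np.linalg.cholesky(target).T
        res = pca_transform(_scores(X.T, n // 2, n // 2), standardize=False)
        assert np.allclose(res.explained_variance_ratio, [0.75, 0.25], atol=1e-9)

    def test_reconstruction(self, rng):
        X = rng.normal(size=(7, 10))
        sm = _scores(X, 5, 5)
        res = pca_transform(sm, standardize=True)
        recon = res.coordinates.to_numpy() @ res.components.to_numpy()
        Z = sm.scores.to_numpy().T
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        assert np.allclose(recon, Z - Z.mean(0), atol=1e-9)

    def test_condition_mean_orientation(self, rng):
        X = rng.normal(size=(5, 12))
        X[:, 6:] += 3.0  # condition samples shifted up in every set
        res = pca_transform(_scores(X, 6, 6))
        pc1 = res.coordinates["PC1"]
        assert pc1.iloc[6:].mean() >= pc1.iloc[:6].mean()

    def test_too_few_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="2 sets"):
            pca_transform(_scores(rng.normal(size=(1, 6)), 3, 3))


class TestPcSeparation:
    def test_identical_coordinates_give_p_one(self):
        X = np.vstack([[1, 2, 3, 1, 2, 3], [5, 6, 7, 5, 6, 7.0]])
        sm = _scores(X, 3, 3)
        res = pca_transform(sm, standardize=False)
        t, p = pc_separation_test(res, sm, component=1)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        ctrl = rng.normal(0, 1, size=(3, 9))
        cond = rng.normal(5, 1, size=(3, 8))
        sm = _scores(np.hstack([ctrl, cond]), 9, 8)
        res = pca_transform(sm)
        t, p = pc_separation_test(res, sm, component=1)
        assert p < 1e-4 and t > 0

    def test_label_swap_negates_t(self, rng):
        X = rng.normal(size=(4, 10))
        sm = _scores(X, 5, 5)
        res = pca_transform(sm)
        t1, p1 = pc_separation_test(res, sm, component=2)
        sm2 = _scores(X, 5, 5)
        sm2.condition = "ctrl"
        t2, p2 = pc_separation_test(res, sm2, component=2)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestRocAuc:
    def _auc(self, ctrl, cond):
        vals = pd.Series(
            list(ctrl) + list(cond),
            index=[f"c{i}" for i in range(len(ctrl))] + [f"t{i}" for i in range(len(cond))],
            dtype=float,
        )
        groups = pd.Series(["ctrl"] * len(ctrl) + ["cond"] * len(cond), index=vals.index)
        return roc_auc(vals, groups, "cond")

    @pytest.mark.parametrize("ctrl,cond,expected", [
        ([1, 2], [3, 4], 1.0),
        ([5, 5], [5, 5], 0.5),
        ([1, 3], [2, 4], 0.75),
    ])
    def test_known_values(self, ctrl, cond, expected):
        auc, roc = self._auc(ctrl, cond)
        assert auc == pytest.approx(expected)
        assert roc["tpr"].iloc[-1] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 26, size=2)
        ctrl = rng.integers(0, 10, size=n1).astype(float)  # integer values force ties
        cond = rng.integers(0, 10, size=n2).astype(float)
        auc, _ = self._auc(ctrl, cond)
        assert auc == pytest.approx(auc_pair_count(ctrl, cond), abs=1e-12)

    def test_label_swap_complements(self, rng):
        ctrl = rng.normal(size=6)
        cond = rng.normal(size=5)
        auc, _ = self._auc(ctrl, cond)
        auc_swapped, _ = self._auc(cond, ctrl)
        assert auc_swapped == pytest.approx(1.0 - auc)

    def test_single_class_rejected(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        groups = pd.Series(["cond", "cond"], index=vals.index)
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(vals, groups, "cond")


class TestResampling:
    def _cohort(self, seed, n_sets=30, shift=0.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_sets, 16))
        X[:4, 8:] += shift  # first four sets carry the signal
        return _scores(X, 8, 8)

    def test_deterministic_under_seed(self):
        cohort = self._cohort(0, shift=2.0)
        cand = cohort.set_names[:4]
        r1 = resample_random_sets([cohort], cand, B=50, component=1, seed=5)
        r2 = resample_random_sets([cohort], cand, B=50, component=1, seed=5)
        assert np.array_equal(r1.null_aucs, r2.null_aucs)
        assert r1.p_right == r2.p_right

    def test_add_one_estimator(self):
        cohort = self._cohort(1, shift=3.0)
        cand = cohort.set_names[:4]
        res = resample_random_sets([cohort], cand, B=100, component=1, seed=7)
        expected = (1 + int((res.null_aucs >= res.observed).sum())) / 101
        assert res.p_right == pytest.approx(expected)
        assert res.p_right >= 1 / 101

    def test_strong_signal_beats_null(self):
        cohorts = [self._cohort(s, shift=4.0) for s in (2, 3)]
        cand = cohorts[0].set_names[:4]
        res = resample_random_sets(cohorts, cand, B=100, component=1, seed=9)
        assert res.observed > 0.95
        assert res.p_right < 0.3  # null draws can contain signal sets

    def test_errors(self):
        cohort = self._cohort(4)
        with pytest.raises(ValueError, match="B must be"):
            resample_random_sets([cohort], cohort.set_names[:3], B=0)
        with pytest.raises(ValueError, match="not scored"):
            resample_random_sets([cohort], ["MISSING", "S0"], B=10)
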