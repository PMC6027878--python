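import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wingmorph.shape_stats import (
    angle_between,
    cva,
    decompose,
    manova_wilks,
    mean_shape_distance_matrix,
    randomized_manova,
    shape_pca,
    trajectory_angles,
)


def _crossed_labels(rng, n_per_cell, stages=("larva", "pupa"), genos=("yw", "ds")):
    s, g = [], []
    for st in stages:
        for ge in genos:
            s += [st] * n_per_cell
            g += [ge] * n_per_cell
    return np.array(s), np.array(g)


class TestPCA:
    def test_variation_in_one_coordinate_pair(self, rng):
        X = np.zeros((30, 10))
        X[:, 2] = rng.normal(size=30)
        X[:, 3] = 0.5 * X[:, 2]
        res = shape_pca(X, n_axes=5)
        assert res.eigenvalues[0] > 0
        assert np.all(res.eigenvalues[1:] < 1e-20)

    def test_trace_conservation(self, rng):
        X = rng.normal(size=(40, 12))
        res = shape_pca(X, n_axes=12)
        total_var = ((X - X.mean(axis=0)) ** 2).sum() / (len(X) - 1)
        assert res.eigenvalues.sum() == pytest.approx(total_var, abs=1e-10)

    def test_svd_oracle_up_to_sign(self, rng):
        X = rng.normal(size=(5, 6))
        res = shape_pca(X, n_axes=4)
        Xc = X - X.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        oracle_scores = u * s
        for a in range(4):
            mine = res.scores[:, a]
            ref = oracle_scores[:, a]
            assert min(np.abs(mine - ref).max(), np.abs(mine + ref).max()) < 1e-10

    def test_scores_reconstruct_within_subspace(self, rng):
        X = rng.normal(size=(25, 8))
        res = shape_pca(X, n_axes=8)
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_rank_truncation_warns(self, rng, caplog):
        X = rng.normal(size=(30, 4))
        X = np.hstack([X, X])  # rank 4 in 8 columns
        with caplog.at_level("WARNING"):
            res = shape_pca(X, n_axes=8)
        assert res.n_axes == 4
        assert "rank" in caplog.text

    def test_sign_convention(self, rng):
        X = rng.normal(size=(20, 6))
        res = shape_pca(X, n_axes=3)
        for a in range(3):
            col = res.loadings[:, a]
            assert col[np.argmax(np.abs(col))] > 0


class TestCVA:
    def test_two_well_separated_classes(self, rng):
        a = rng.normal(scale=0.01, size=(20, 2))
        b = rng.normal(scale=0.01, size=(20, 2)) + [10.0, 0.0]
        res = cva(np.vstack([a, b]), ["a"] * 20 + ["b"] * 20)
        assert res.scores.shape[1] == 1
        gap = abs(res.class_means[0, 0] - res.class_means[1, 0])
        assert gap > 100  # canonical scores have within-class SD ~1

    def test_within_class_sphering(self, rng):
        X = rng.normal(size=(60, 4))
        X[20:40] += [3, 0, 0, 0]
        X[40:] += [0, 3, 0, 0]
        labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        res = cva(X, labels)
        n, k = 60, 3
        pooled = np.zeros((res.scores.shape[1],) * 2)
        for c in set(labels):
            sc = res.scores[np.array(labels) == c]
            dev = sc - sc.mean(axis=0)
            pooled += dev.T @ dev
        pooled /= n - k
        np.testing.assert_allclose(pooled, np.eye(len(pooled)), atol=1e-8)

    def test_permuted_labels_no_separation(self, rng):
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3)) + [8, 0, 0]
        X = np.vstack([a, b])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        structured = cva(X, labels).eigenvalues[0]
        permuted = cva(X, rng.permutation(labels)).eigenvalues[0]
        assert permuted < 0.15 * structured

    def test_three_stage_clusters_disjoint(self, aligned_small):
        res_pca = shape_pca(aligned_small.shapes, n_axes=10)
        res = cva(res_pca.scores, aligned_small.stages)
        assert res.scores.shape[1] == 2
        labels = np.array(aligned_small.stages)
        # convex separation proxy: nearest between-class pair farther apart
        # than each class's span on the first canonical axis
        for c1 in set(labels):
            for c2 in set(labels) - {c1}:
                m1 = res.scores[labels == c1, 0]
                m2 = res.scores[labels == c2, 0]
                assert (m1.max() < m2.min()) or (m2.max() < m1.min())

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            cva(X, ["a", "a", "a", "a", "b"])


class TestManovaWilks:
    def test_hand_computed_two_group_case(self):
        # groups {0,1} and {2,3}: E = 0.5+0.5 = 1, H = 4, lambda = 0.2
        y = np.array([0.0, 1.0, 2.0, 3.0])
        res = manova_wilks(y, {"group": ["a", "a", "b", "b"]}, "group", interactions=[])
        assert res.wilks_lambda == pytest.approx(0.2, abs=1e-12)

    def test_lambda_in_unit_interval(self, rng):
        stages, genos = _crossed_labels(rng, 8)
        Y = rng.normal(size=(len(stages), 3))
        for eff in ("stage", "genotype", "stage:genotype"):
            res = manova_wilks(Y, {"stage": stages, "genotype": genos}, eff)
            assert 0 < res.wilks_lambda <= 1

    def test_against_statsmodels_reference(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        n_cell = 9
        stages, genos = _crossed_labels(rng, n_cell, ("l", "p", "a"), ("u", "v"))
        Y = rng.normal(size=(len(stages), 4))
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3", "y4"])
        df["s"], df["g"] = stages, genos
        ref = MANOVA.from_formula(
            "y1 + y2 + y3 + y4 ~ C(s, Sum) * C(g, Sum)", data=df
        ).mv_test()
        pairs = [("stage", "C(s, Sum)"), ("genotype", "C(g, Sum)"),
                 ("stage:genotype", "C(s, Sum):C(g, Sum)")]
        for eff, key in pairs:
            mine = manova_wilks(Y, {"stage": stages, "genotype": genos}, eff)
            tbl = ref.results[key]["stat"]
            assert mine.wilks_lambda == pytest.approx(
                float(tbl.loc["Wilks' lambda", "Value"]), abs=1e-8)
            assert mine.F == pytest.approx(
                float(tbl.loc["Wilks' lambda", "F Value"]), rel=1e-8)
            assert mine.p_value == pytest.approx(
                float(tbl.loc["Wilks' lambda", "Pr > F"]), abs=1e-10)

    def test_response_dim_guard(self, rng):
        stages, genos = _crossed_labels(rng, 2)
        Y = rng.normal(size=(len(stages), 6))
        with pytest.raises(ValueError, match="error df"):
            manova_wilks(Y, {"stage": stages, "genotype": genos}, "genotype")

    def test_unknown_effect(self, rng):
        stages, genos = _crossed_labels(rng, 4)
        Y = rng.normal(size=(len(stages), 2))
        with pytest.raises(ValueError, match="effect"):
            manova_wilks(Y, {"stage": stages, "genotype": genos}, "sex")


class TestDecompose:
    def test_reconstruction_identity_unbalanced(self, rng):
        n = 67
        stages = rng.choice(["larva", "pupa", "adult"], size=n)
        genos = rng.choice(["yw", "ds", "shf2"], size=n)
        # ensure every cell occupied
        fill = [(s, g) for s in ("larva", "pupa", "adult") for g in ("yw", "ds", "shf2")]
        for i, (s, g) in enumerate(fill):
            stages[i], genos[i] = s, g
        Y = rng.normal(size=(n, 5))
        for weighted in (False, True):
            dec = decompose(Y, stages, genos, weighted=weighted)
            np.testing.assert_allclose(dec.reconstruct(), Y, atol=1e-12)

    def test_one_observation_per_cell_zero_deviation(self, rng):
        stages, genos = _crossed_labels(rng, 1, ("l", "p"), ("u", "v"))
        Y = rng.normal(size=(4, 3))
        dec = decompose(Y, stages, genos)
        np.testing.assert_allclose(dec.deviations, 0, atol=1e-12)

    def test_identical_observations_all_terms_zero(self):
        stages, genos = _crossed_labels(np.random.default_rng(0), 3)
        Y = np.tile([1.0, 2.0], (len(stages), 1))
        dec = decompose(Y, stages, genos)
        for term in (dec.stage_terms, dec.genotype_terms, dec.interaction_terms, dec.deviations):
            np.testing.assert_allclose(term, 0, atol=1e-12)

    def test_unweighted_terms_sum_to_zero_over_levels(self, rng):
        stages, genos = _crossed_labels(rng, 5, ("l", "p", "a"), ("u", "v", "w"))
        Y = rng.normal(size=(len(stages), 4))
        dec = decompose(Y, stages, genos)
        stage_levels = {s: dec.stage_terms[stages == s][0] for s in set(stages)}
        np.testing.assert_allclose(sum(stage_levels.values()), 0, atol=1e-12)

    def test_empty_cell_raises(self, rng):
        stages = np.array(["l"] * 4 + ["p"] * 4)
        genos = np.array(["u", "u", "v", "v", "u", "u", "u", "u"])
        Y = rng.normal(size=(8, 2))
        with pytest.raises(ValueError, match="empty"):
            decompose(Y, stages, genos)


class TestRandomizedManova:
    def test_p_value_lower_bound(self, rng):
        stages, genos = _crossed_labels(rng, 6, ("l", "p", "a"), ("u", "v", "w"))
        Y = rng.normal(size=(len(stages), 4))
        res = randomized_manova(Y, stages, genos, "genotype", n_rand=99, seed=0)
        assert res.p_value >= 1.0 / 100.0
        assert np.all((res.null_lambdas > 0) & (res.null_lambdas <= 1))

    def test_strong_effect_below_all_nulls(self, rng):
        stages, genos = _crossed_labels(rng, 8, ("l", "p", "a"), ("u", "v", "w"))
        Y = rng.normal(size=(len(stages), 4))
        shift = {"u": 0.0, "v": 5.0, "w": -5.0}
        Y[:, 0] += np.array([shift[g] for g in genos])
        res = randomized_manova(Y, stages, genos, "genotype", n_rand=500, seed=1)
        assert res.observed_lambda < res.null_lambdas.min()
        assert res.p_value == pytest.approx(1.0 / 501.0)

    def test_interaction_permutation_within_stage(self, rng):
        stages, genos = _crossed_labels(rng, 8, ("l", "p"), ("u", "v", "w"))
        Y = rng.normal(size=(len(stages), 3))
        res = randomized_manova(Y, stages, genos, "stage:genotype", n_rand=99, seed=2)
        assert res.effect == "stage:genotype"
        assert 0 < res.p_value <= 1

    def test_determinism(self, rng):
        stages, genos = _crossed_labels(rng, 6)
        Y = rng.normal(size=(len(stages), 3))
        r1 = randomized_manova(Y, stages, genos, "genotype", n_rand=50, seed=42)
        r2 = randomized_manova(Y, stages, genos, "genotype", n_rand=50, seed=42)
        np.testing.assert_array_equal(r1.null_lambdas, r2.null_lambdas)

    def test_unknown_effect(self, rng):
        stages, genos = _crossed_labels(rng, 4)
        Y = rng.normal(size=(len(stages), 2))
        with pytest.raises(ValueError):
            randomized_manova(Y, stages, genos, "stage", n_rand=10, seed=0)

    def test_null_pvalues_super_uniform(self):
        # KS test over replicates of a true null must not reject at 1%
        rng = np.random.default_rng(7)
        stages, genos = _crossed_labels(rng, 6, ("l", "p", "a"), ("u", "v", "w"))
        pvals = []
        for rep in range(500):
            Y = rng.normal(size=(len(stages), 3))
            res = randomized_manova(Y, stages, genos, "genotype",
                                    n_rand=99, seed=rep)
            pvals.append(res.p_value)
        stat, p = stats.kstest(pvals, "uniform")
        # add-one estimator is slightly conservative: demand no anti-
        # conservative deviation and overall closeness to uniform
        assert p > 0.01 or np.mean(np.array(pvals) <= 0.05) <= 0.07


class TestDistanceMatrix:
    def test_identical_specimens_zero(self):
        Y = np.ones((8, 4))
        stages = ["l"] * 4 + ["p"] * 4
        genos = ["u", "u", "v", "v"] * 2
        m = mean_shape_distance_matrix(Y, stages, genos)
        np.testing.assert_allclose(m.to_numpy(), 0, atol=1e-12)

    def test_two_singletons_delta(self):
        Y = np.zeros((2, 4))
        Y[1, 2] = 0.25
        m = mean_shape_distance_matrix(Y, ["l", "p"], ["u", "u"])
        assert m.loc["l:u", "p:u"] == pytest.approx(0.25, abs=1e-12)
        assert np.isnan(m.loc["l:u", "l:u"])  # singleton diagonal missing

    def test_brute_force_oracle(self, rng):
        Y = rng.normal(size=(14, 6))
        stages = np.array(["l"] * 7 + ["p"] * 7)
        genos = np.array(["u", "u", "u", "v", "v", "v", "v"] * 2)
        m = mean_shape_distance_matrix(Y, stages, genos)
        groups = {}
        for i in range(14):
            groups.setdefault(f"{stages[i]}:{genos[i]}", []).append(Y[i])
        for la, va in groups.items():
            for lb, vb in groups.items():
                acc = []
                for i, a in enumerate(va):
                    for j, b in enumerate(vb):
                        if la == lb and i >= j:
                            continue
                        acc.append(np.linalg.norm(a - b))
                assert m.loc[la, lb] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_symmetry_nonnegative(self, aligned_small):
        m = mean_shape_distance_matrix(aligned_small.shapes, aligned_small.stages,
                                       aligned_small.genotypes)
        v = m.to_numpy()
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert np.nanmin(v) >= 0

    def test_between_stage_exceeds_within_stage(self, aligned_small):
        m = mean_shape_distance_matrix(
            aligned_small.shapes, aligned_small.stages, aligned_small.genotypes,
            stage_order=["larva", "pupa", "adult"])
        lab = [l.split(":")[0] for l in m.index]
        within, between = [], []
        for i in range(len(lab)):
            for j in range(i, len(lab)):
                (within if lab[i] == lab[j] else between).append(m.iloc[i, j])
        assert np.nanmean(between) > 2.0 * np.nanmean(within)


class TestTrajectoryAngles:
    def test_identical_transformations_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert angle_between(v, 2.0 * v) == pytest.approx(0, abs=1e-9)

    def test_orthogonal_ninety(self):
        v1 = np.zeros(34); v1[0] = 1.0
        v2 = np.zeros(34); v2[1] = 1.0
        assert angle_between(v1, v2) == pytest.approx(90.0, abs=1e-12)

    def test_symmetric_and_scale_invariant(self, rng):
        v1, v2 = rng.normal(size=34), rng.normal(size=34)
        a = angle_between(v1, v2)
        assert angle_between(v2, v1) == pytest.approx(a, abs=1e-12)
        assert angle_between(3.7 * v1, 0.2 * v2) == pytest.approx(a, abs=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError, match="zero-length"):
            angle_between(np.zeros(4), np.ones(4))

    def test_range_and_diagonal(self, aligned_small):
        mats = trajectory_angles(aligned_small.shapes, aligned_small.stages,
                                 aligned_small.genotypes)
        assert set(mats) == {("larva", "pupa"), ("pupa", "adult"), ("larva", "adult")}
        for mat in mats.values():
            v = mat.to_numpy()
            assert np.all((v >= 0) & (v <= 180))
            np.testing.assert_allclose(np.diag(v), 0, atol=1e-12)

    def test_missing_stage_raises(self, rng):
        Y = rng.normal(size=(4, 6))
        with pytest.raises(ValueError, match="missing"):
            trajectory_angles(Y, ["larva"] * 4, ["yw", "yw", "ds", "ds"],
                              transitions=[("larva", "adult")])
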