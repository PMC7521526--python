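"""PCA compression, CCA against a generalized-eigenproblem oracle,
permutation inference, structure correlations."""

import numpy as np
import pytest
from scipy import linalg

from longimode import (SubjectMatrix, build_default_registry, cca,
                       debias_canonical_correlation, pca_reduce,
                       permutation_inference, structure_correlations,
                       subdomain_importance)
from longimode.cca import CCAResult


def cca_oracle(X, Y):
    """Brute-force canonical correlations: eigenvalues of
    Sxx^-1 Sxy Syy^-1 Syx (squared canonical correlations)."""
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    n = X.shape[0]
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.sort(np.real(linalg.eigvals(M)))[::-1]
    k = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(ev[:k], 0, 1))


def imputed(values, prefix="v"):
    values = np.asarray(values, dtype=float)
    return SubjectMatrix([f"S{i}" for i in range(values.shape[0])],
                         [f"{prefix}{j}" for j in range(values.shape[1])],
                         values, provenance="imputed")


class TestPCAReduce:
    def test_exact_rank_two_full_variance(self, rng):
        u = rng.standard_normal((12, 2))
        v = rng.standard_normal((2, 6))
        red = pca_reduce(imputed(u @ v), k=2)
        assert red.cumulative_variance[-1] == pytest.approx(1.0)

    def test_duplicated_column_same_subspace(self, rng):
        x = rng.standard_normal((15, 1))
        r1 = pca_reduce(imputed(x), k=1)
        r2 = pca_reduce(imputed(np.hstack([x, x])), k=1)
        c = np.corrcoef(r1.scores[:, 0], r2.scores[:, 0])[0, 1]
        assert abs(c) == pytest.approx(1.0)

    def test_eckart_young_reconstruction_identity(self, rng):
        X = rng.standard_normal((20, 9))
        m = imputed(X)
        k = 4
        red = pca_reduce(m, k)
        Xc = X - X.mean(0)
        recon = red.scores @ red.loadings.T
        err = np.linalg.norm(Xc - recon) ** 2
        s = np.linalg.svd(Xc, compute_uv=False)
        assert err == pytest.approx(float((s[k:] ** 2).sum()), rel=1e-10)

    def test_k_reduced_to_rank_with_warning(self, rng):
        u = rng.standard_normal((10, 2))
        v = rng.standard_normal((2, 5))
        with pytest.warns(UserWarning, match="rank"):
            red = pca_reduce(imputed(u @ v), k=5)
        assert red.k == 2

    def test_scores_orthogonal(self, rng):
        red = pca_reduce(imputed(rng.standard_normal((25, 10))), k=6)
        G = red.scores.T @ red.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)


class TestCCAOracle:
    def test_fixed_six_subject_fixture(self):
        X = np.array([[1.0, 0.2], [2.0, -0.3], [0.5, 1.1],
                      [-1.2, 0.7], [0.3, -1.4], [-0.8, 0.9]])
        Y = np.array([[0.9, -0.1], [1.8, 0.4], [0.2, 1.0],
                      [-1.0, 0.5], [0.6, -1.1], [-1.1, 1.2]])
        res = cca(X, Y)
        assert np.allclose(res.correlations, cca_oracle(X, Y), atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        px = int(rng.integers(1, min(5, n - 1) + 1))
        py = int(rng.integers(1, min(5, n - 1) + 1))
        X = rng.standard_normal((n, px))
        Y = rng.standard_normal((n, py))
        res = cca(X, Y)
        assert np.allclose(res.correlations, cca_oracle(X, Y), atol=1e-10)

    def test_self_correlation_all_ones(self, rng):
        X = rng.standard_normal((12, 4))
        res = cca(X, X.copy())
        assert np.allclose(res.correlations, 1.0, atol=1e-10)

    def test_joint_row_permutation_invariance(self, rng):
        X = rng.standard_normal((15, 3))
        Y = rng.standard_normal((15, 4))
        perm = rng.permutation(15)
        a = cca(X, Y).correlations
        b = cca(X[perm], Y[perm]).correlations
        assert np.allclose(a, b, atol=1e-10)

    def test_variates_satisfy_invariants(self, rng):
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 3))
        res = cca(X, Y)
        assert np.all(np.diff(res.correlations) <= 1e-12)  # sorted
        for i in range(res.n_modes):
            assert res.U[:, i].std(ddof=1) == pytest.approx(1.0)
            assert res.V[:, i].std(ddof=1) == pytest.approx(1.0)
            r = np.corrcoef(res.U[:, i], res.V[:, i])[0, 1]
            assert r == pytest.approx(res.correlations[i], abs=1e-10)
            for j in range(i + 1, res.n_modes):
                assert abs(np.corrcoef(res.U[:, i], res.U[:, j])[0, 1]) < 1e-8
                assert abs(np.corrcoef(res.V[:, i], res.V[:, j])[0, 1]) < 1e-8

    def test_sign_convention_deterministic(self, rng):
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 3))
        res = cca(X, Y)
        for i in range(res.n_modes):
            assert res.weights_y[:, i].sum() >= 0

    def test_rank_deficiency_rejected_by_default(self, rng):
        x = rng.standard_normal((10, 1))
        X = np.hstack([x, x])
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            cca(X, rng.standard_normal((10, 2)))
        res = cca(X, rng.standard_normal((10, 2)), on_deficiency="regularize")
        assert res.n_modes == 1


class TestPermutationInference:
    def test_planted_mode_attains_floor(self, rng):
        n = 40
        u = rng.standard_normal((n, 1))
        X = np.hstack([u + 0.1 * rng.standard_normal((n, 1)) for _ in range(2)])
        Y = np.hstack([0.95 * u + np.sqrt(1 - 0.95**2) * 0.3 *
                       rng.standard_normal((n, 1)) for _ in range(2)])
        inf = permutation_inference(X, Y, n_perm=999, seed=0)
        assert inf.p_fwe[0] == pytest.approx(1 / 1000)

    def test_p_nondecreasing_across_modes(self, rng):
        X = rng.standard_normal((25, 4))
        Y = rng.standard_normal((25, 3))
        inf = permutation_inference(X, Y, n_perm=199, seed=3)
        assert np.all(np.diff(inf.p_fwe) >= 0)
        assert inf.p_fwe.min() >= 1 / 200

    def test_seed_reproducibility(self, rng):
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 3))
        a = permutation_inference(X, Y, n_perm=150, seed=9)
        b = permutation_inference(X, Y, n_perm=150, seed=9)
        assert np.array_equal(a.null_max, b.null_max)

    def test_low_n_perm_warns(self, rng):
        with pytest.warns(UserWarning, match="coarse"):
            permutation_inference(rng.standard_normal((12, 2)),
                                  rng.standard_normal((12, 2)), n_perm=50, seed=0)


class TestDebiasing:
    @pytest.mark.parametrize("rho", [0.6, 0.75, 0.9])
    def test_inverts_forward_spiked_relation(self, rho):
        n, kx, ky = 123, 30, 30
        c1, c2 = kx / n, ky / n
        lam = rho**2
        lam_hat = (lam + c1 * (1 - lam)) * (lam + c2 * (1 - lam)) / lam
        est = debias_canonical_correlation(np.sqrt(lam_hat), n, kx, ky)
        assert est == pytest.approx(rho, abs=1e-10)

    def test_no_components_no_correction(self):
        # c -> 0 limit: estimate equals the observed value
        assert debias_canonical_correlation(0.8, 10**7, 1, 1) == \
            pytest.approx(0.8, abs=1e-3)

    def test_below_threshold_returns_threshold(self):
        n, k = 123, 30
        c = k / n
        thr = np.sqrt(np.sqrt(c * c / ((1 - c) * (1 - c))))
        assert debias_canonical_correlation(0.0, n, k, k) == pytest.approx(thr)


class TestStructureCorrelations:
    def build(self, rng, loadings=(0.9, 0.0, -0.9), n=123):
        reg = build_default_registry("toy")
        ids = reg.ids(block="behavioural")[: len(loadings)]
        u = rng.standard_normal(n)
        vals = np.column_stack([l * u + 0.3 * rng.standard_normal(n)
                                for l in loadings])
        raw = SubjectMatrix([f"S{i}" for i in range(n)], ids, vals,
                            provenance="deconfounded")
        res = CCAResult(weights_x=np.eye(1), weights_y=np.eye(1),
                        U=(u / u.std(ddof=1)).reshape(-1, 1),
                        V=(u / u.std(ddof=1)).reshape(-1, 1),
                        correlations=np.array([1.0]))
        return res, raw, reg, ids

    def test_self_variable_r_one(self, rng):
        res, raw, reg, ids = self.build(rng)
        raw.values[:, 0] = res.U[:, 0]
        sc = structure_correlations(res, 0, raw, reg, "behavioural")
        assert sc.table["r"].iloc[0] == pytest.approx(1.0)
        assert sc.table["r2"].iloc[0] == pytest.approx(1.0)

    def test_loading_signs_recovered(self):
        """Planted loadings (0.9, 0, -0.9) at n=123, 20 seeds: recovered
        structure correlations sign-match in every draw and the
        zero-loading variable falls below the 0.2 reporting filter in
        the vast majority of draws (its sampling sd is ~1/sqrt(123))."""
        below_filter = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            res, raw, reg, ids = self.build(rng)
            sc = structure_correlations(res, 0, raw, reg, "behavioural")
            r = sc.table.set_index("variable_id")["r"]
            assert r[ids[0]] > 0.2
            assert r[ids[2]] < -0.2
            assert abs(r[ids[1]]) < r[ids[0]]
            below_filter += abs(r[ids[1]]) < 0.2
        assert below_filter >= 0.8 * n_rep

    def test_r2_sum_bounded_by_variable_count(self, rng):
        res, raw, reg, _ = self.build(rng)
        sc = structure_correlations(res, 0, raw, reg, "behavioural")
        assert sc.table["r2"].sum() <= len(sc.table)

    def test_mode_index_out_of_range(self, rng):
        res, raw, reg, _ = self.build(rng)
        with pytest.raises(ValueError, match="out of range"):
            structure_correlations(res, 5, raw, reg, "behavioural")


class TestOrientModes:
    def test_behavioural_structure_sum_nonnegative(self, toy_cohort, toy_runconfig):
        from longimode import orient_modes
        from longimode.pipeline import analyze_cohort
        res = analyze_cohort(toy_cohort, toy_runconfig)
        raw = res["beh_deconfounded"]
        oriented = orient_modes(res["cca"], raw)
        for i in range(oriented.n_modes):
            total = 0.0
            for j in range(len(raw.variables)):
                obs = ~raw.mask[:, j]
                x = raw.values[obs, j]
                if len(x) >= 3 and x.std() > 0:
                    total += np.corrcoef(x, oriented.V[obs, i])[0, 1]
            assert total >= 0 or abs(total) < 1e-9
        # orientation is an involution-safe flip: correlations unchanged
        assert np.array_equal(oriented.correlations, res["cca"].correlations)
        # and per-mode variate pairs flip together
        for i in range(oriented.n_modes):
            r_new = np.corrcoef(oriented.U[:, i], oriented.V[:, i])[0, 1]
            assert r_new == pytest.approx(oriented.correlations[i], abs=1e-8)


class TestSubdomainImportance:
    def make_sc(self, rows):
        import pandas as pd
        from longimode.cca import StructureCorrelations
        df = pd.DataFrame(rows)
        df["r2"] = df["r"] ** 2
        df["reported"] = df["r"].abs() >= 0.2
        return StructureCorrelations(0, df)

    def test_constant_r_gives_constant_importance(self, full_registry):
        rows = [{"variable_id": f"v{i}", "block": "IDP",
                 "subdomain": s, "r": 0.4, "n_pairs": 10}
                for i, s in enumerate(["A", "A", "B"])]
        imp = subdomain_importance(self.make_sc(rows), full_registry)
        assert np.allclose(imp["mean_r2"], 0.16)

    def test_symmetric_split_masses_equal(self, full_registry):
        rows = [{"variable_id": "v0", "block": "behavioural",
                 "subdomain": "A", "r": 0.5, "n_pairs": 10},
                {"variable_id": "v1", "block": "behavioural",
                 "subdomain": "A", "r": -0.5, "n_pairs": 10}]
        imp = subdomain_importance(self.make_sc(rows), full_registry)
        assert imp["mean_r2"].iloc[0] == pytest.approx(0.25)
        assert imp["mean_r2_positive"].iloc[0] == \
            pytest.approx(imp["mean_r2_negative"].iloc[0]) == pytest.approx(0.125)

    def test_full_scale_idp_block_groups_into_six(self, toy_cohort, toy_runconfig):
        from longimode.pipeline import analyze_cohort
        res = analyze_cohort(toy_cohort, toy_runconfig)
        sc = structure_correlations(res["cca"], 0, res["idp_deconfounded"],
                                    toy_cohort.registry, "IDP")
        imp = subdomain_importance(sc, toy_cohort.registry)
        assert len(imp) == 6


class TestGroupSeparationUnderNull:
    def test_variates_show_no_egd_clustering(self):
        """With the planted mode independent of the selection residual,
        the mode-1 variate does not separate improvers from decliners
        beyond chance (two-sample t-test rejection rate near alpha)."""
        from scipy import stats as sps
        from longimode import CohortConfig, generate_cohort
        from longimode.pipeline import RunConfig, analyze_cohort
        rejections = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = CohortConfig(n_pool=400, n_select=60, group_sizes=(32, 28),
                               profile="toy", rho_star=0.0, seed=900 + seed)
            cohort = generate_cohort(cfg)
            res = analyze_cohort(cohort, RunConfig.toy(seed=seed))
            u = res["cca"].U[:, 0]
            grp = cohort.group_labels == "improver"
            _, p = sps.ttest_ind(u[grp], u[~grp])
            rejections += p <= 0.05
        # binomial(20, 0.05): >= 5 rejections has probability < 0.003
        assert rejections <= 4
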