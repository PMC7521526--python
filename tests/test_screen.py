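"""Mass-univariate screen: complete pairs, multiplicity, EGD split."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longimode import (SubjectMatrix, benjamini_hochberg_cutoff,
                       correct_multiplicity, manhattan_export,
                       pairwise_pearson, split_group_screen)


def block(values, mask=None, prefix="x", provenance="deconfounded"):
    values = np.asarray(values, dtype=float)
    return SubjectMatrix([f"S{i}" for i in range(values.shape[0])],
                         [f"{prefix}{j}" for j in range(values.shape[1])],
                         values, mask, provenance)


class TestPairwisePearson:
    def test_exact_linear_relation(self, rng):
        x = rng.standard_normal((20, 1))
        rec = pairwise_pearson(block(x), block(2 * x + 1, prefix="y"), "longitudinal")
        assert rec["r"].iloc[0] == pytest.approx(1.0)

    def test_null_correlation_gives_p_one(self):
        x = np.array([[1.0], [-1.0], [1.0], [-1.0], [1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([[1.0], [1.0], [-1.0], [-1.0], [1.0], [1.0], [-1.0], [-1.0]])
        rec = pairwise_pearson(block(x), block(y, prefix="y"), "longitudinal",
                               df_adjust=0)
        assert rec["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert rec["p"].iloc[0] == pytest.approx(1.0)

    def test_complete_pair_handling_matches_scalar_oracle(self, rng):
        """Vectorized masked screen equals a per-pair scipy.pearsonr loop
        over complete pairs."""
        n = 40
        Xv, Yv = rng.standard_normal((n, 4)), rng.standard_normal((n, 3))
        Xm = rng.random((n, 4)) < 0.25
        Ym = rng.random((n, 3)) < 0.25
        rec = pairwise_pearson(block(Xv, Xm), block(Yv, Ym, prefix="y"),
                               "longitudinal", df_adjust=0)
        for row in rec.itertuples():
            i = int(row.id_x[1:])
            j = int(row.id_y[1:])
            keep = ~Xm[:, i] & ~Ym[:, j]
            r_ref, p_ref = stats.pearsonr(Xv[keep, i], Yv[keep, j])
            assert row.r == pytest.approx(r_ref, abs=1e-12)
            assert row.p == pytest.approx(p_ref, rel=1e-9)
            assert row.n_pairs == keep.sum()

    def test_degenerate_variance_flagged(self, rng):
        Xv = np.ones((10, 1))
        rec = pairwise_pearson(block(Xv), block(rng.standard_normal((10, 1)),
                                                prefix="y"), "longitudinal")
        assert not rec["valid"].iloc[0]
        assert np.isnan(rec["r"].iloc[0])

    def test_df_adjustment_reduces_significance(self, rng):
        x = rng.standard_normal((20, 1))
        y = x + 0.7 * rng.standard_normal((20, 1))
        p0 = pairwise_pearson(block(x), block(y, prefix="y"), "s",
                              df_adjust=0)["p"].iloc[0]
        p5 = pairwise_pearson(block(x), block(y, prefix="y"), "s",
                              df_adjust=5)["p"].iloc[0]
        assert p5 > p0

    def test_raw_provenance_rejected(self, rng):
        m = block(rng.standard_normal((10, 1)), provenance="deconfounded")
        raw = block(rng.standard_normal((10, 1)), prefix="y", provenance="raw")
        from longimode import ProvenanceError
        with pytest.raises(ProvenanceError):
            pairwise_pearson(m, raw, "s")


class TestEnumerationCounts:
    """Record counts equal |X columns| x |Y columns| at the cohort scale."""

    def test_longitudinal_screen_enumerates_51756(self, full_registry, rng):
        n = 8
        X = block(rng.standard_normal((n, 454)))
        Y = block(rng.standard_normal((n, 114)), prefix="y")
        rec = pairwise_pearson(X, Y, "longitudinal")
        assert len(rec) == 51756

    def test_cross_sectional_and_cognitive_counts(self, full_registry):
        # enumeration identities printed for the cohort
        assert 454 * 114 == 51756
        assert 453 * 114 == 51642
        assert len(full_registry.xs_behavioural_sources) * 454 == 31780
        n_cog = len(full_registry.ids(domain="cognitive"))
        n_other = 114 - n_cog
        assert n_cog * n_other == 3200


class TestMultiplicity:
    def test_step_up_worked_example(self):
        rec = pd.DataFrame({"p": [0.001, 0.02, 0.03, 0.04], "valid": True})
        thr = correct_multiplicity(rec, alpha=0.05)
        # step-up: p(4)=0.04 <= 4*0.05/4 -> all four discovered
        assert thr.bh_p == 0.04
        assert thr.n_discoveries_fdr == 4
        assert thr.bonferroni_p == 0.0125
        assert thr.n_discoveries_fwe == 1

    def test_all_null_no_discoveries(self):
        rec = pd.DataFrame({"p": np.ones(10), "valid": True})
        thr = correct_multiplicity(rec)
        assert thr.n_discoveries_fdr == 0 == thr.n_discoveries_fwe
        assert thr.bh_p == 0.0

    def test_bonferroni_never_exceeds_bh(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(5, 60))
            rec = pd.DataFrame({"p": p, "valid": True})
            thr = correct_multiplicity(rec)
            assert thr.n_discoveries_fwe <= thr.n_discoveries_fdr or \
                thr.n_discoveries_fdr == 0 and thr.n_discoveries_fwe == 0

    def test_step_up_equals_brute_force_oracle(self, rng):
        """BH cutoff equals brute-force maximization of
        {i : p(i) <= i*alpha/m} on random p-vectors, and the discovery
        set matches statsmodels."""
        from statsmodels.stats.multitest import multipletests
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            alpha = float(rng.choice([0.01, 0.05, 0.2]))
            cut = benjamini_hochberg_cutoff(p, alpha)
            ps = np.sort(p)
            winners = [ps[i] for i in range(m) if ps[i] <= (i + 1) * alpha / m]
            assert cut == (max(winners) if winners else 0.0)
            reject_sm = multipletests(p, alpha=alpha, method="fdr_bh")[0]
            assert np.array_equal(p <= cut if cut > 0 else np.zeros(m, bool),
                                  reject_sm)


class TestManhattanExport:
    def test_empty_records_header_only(self, full_registry):
        rec = pd.DataFrame(columns=["id_x", "id_y", "r", "n_pairs", "p",
                                    "neg_log10_p", "analysis_set", "valid"])
        out = manhattan_export(rec, full_registry)
        assert len(out) == 0
        assert "line_fwe_p" in out.columns

    def test_rows_ordered_and_annotated(self, toy_registry, rng):
        ids_x = toy_registry.ids(block="IDP")[:3]
        ids_y = toy_registry.ids(block="behavioural")[:2]
        X = SubjectMatrix([f"S{i}" for i in range(12)], ids_x,
                          rng.standard_normal((12, 3)), provenance="deconfounded")
        Y = SubjectMatrix([f"S{i}" for i in range(12)], ids_y,
                          rng.standard_normal((12, 2)), provenance="deconfounded")
        rec = pairwise_pearson(X, Y, "longitudinal")
        out = manhattan_export(rec, toy_registry,
                               override_lines={"fwe": 6.01e-6})
        assert list(out["id_y"][:3]) == [ids_y[0]] * 3
        assert set(out["subdomain_x"]) <= set(toy_registry.subdomains("IDP"))
        assert (out["line_fwe_override_p"] == 6.01e-6).all()

    def test_mixed_sets_rejected(self, full_registry):
        rec = pd.DataFrame({"id_x": ["a", "b"], "id_y": ["c", "d"],
                            "p": [0.5, 0.5], "valid": True,
                            "analysis_set": ["s1", "s2"]})
        with pytest.raises(ValueError, match="mix"):
            manhattan_export(rec, full_registry)


class TestSplitGroupScreen:
    def test_single_group_equals_pooled(self, rng):
        X = block(rng.standard_normal((20, 3)))
        Y = block(rng.standard_normal((20, 2)), prefix="y")
        res = split_group_screen(X, Y, ["a"] * 20)
        assert np.allclose(res["a"]["r"], res["pooled"]["r"], equal_nan=True)

    def test_label_swap_exchanges_results(self, rng):
        X = block(rng.standard_normal((24, 2)))
        Y = block(rng.standard_normal((24, 2)), prefix="y")
        labels = np.array(["a"] * 12 + ["b"] * 12)
        r1 = split_group_screen(X, Y, labels)
        r2 = split_group_screen(X, Y, np.where(labels == "a", "b", "a"))
        # relabelled groups exchange exactly
        assert np.allclose(r1["a"]["r"], r2["b"]["r"], equal_nan=True)
        assert np.allclose(r1["b"]["r"], r2["a"]["r"], equal_nan=True)
        assert np.allclose(r1["pooled"]["r"], r2["pooled"]["r"], equal_nan=True)

    def test_simpsons_paradox_made_visible(self, rng):
        """Two clusters with a pure between-group mean shift and zero
        within-group correlation: pooled |r| is large, within-group
        |r| is near zero, and the comparison table exposes the excess.

        With group means +/-d on both axes and unit within-group
        variance, the pooled correlation is d^2/(1+d^2) analytically."""
        n, d = 300, 3.0
        g = np.repeat([1.0, -1.0], n // 2)
        x = d * g + rng.standard_normal(n)
        y = d * g + rng.standard_normal(n)
        X = block(x.reshape(-1, 1))
        Y = block(y.reshape(-1, 1), prefix="y")
        labels = np.where(g > 0, "a", "b")
        res = split_group_screen(X, Y, labels)
        pooled_r = res["pooled"]["r"].iloc[0]
        assert pooled_r == pytest.approx(d**2 / (1 + d**2), abs=0.08)
        assert abs(res["a"]["r"].iloc[0]) < 0.2
        assert abs(res["b"]["r"].iloc[0]) < 0.2
        assert res["comparison"]["pooled_excess"].iloc[0] > 0.5

    def test_small_group_warns(self, rng):
        X = block(rng.standard_normal((12, 1)))
        Y = block(rng.standard_normal((12, 1)), prefix="y")
        with pytest.warns(UserWarning, match="only"):
            split_group_screen(X, Y, ["a"] * 7 + ["b"] * 5)
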