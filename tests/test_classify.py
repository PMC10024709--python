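"""Tests for the PCA + k-means pipeline, ROC/Youden and group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dynaclamp.classify import (
    APD_FAMILY,
    FEATURE_COLUMNS,
    classify_by_cutoff,
    cluster_cohort,
    kmeans2,
    levene_w,
    mann_whitney_u,
    roc_youden,
    standardize_and_pca2,
)


def _toy_table(n=20, seed=0):
    """Synthetic biomarker table with two separated phenotype groups."""
    rng = np.random.default_rng(seed)
    half = n // 2
    rows = []
    for i in range(n):
        atrial = i < half
        apd90 = rng.normal(120 if atrial else 380, 15)
        ratio = rng.normal(0.15 if atrial else 0.55, 0.03)
        rows.append({
            "Cm_pF": rng.normal(45, 5),
            "Ediast_mV": rng.normal(-60, 3),
            "EdiastDC_mV": rng.normal(-88, 2),
            "APD90_ms": apd90,
            "APD50_ms": apd90 * rng.normal(0.8, 0.02),
            "APD20_ms": apd90 * ratio,
            "APD20_APD90": ratio,
            "dVdtmax_Vps": rng.normal(150, 20),
            "APA_mV": rng.normal(140, 5),
            "phenotype": "atrial" if atrial else "ventricular",
        })
    return pd.DataFrame(rows)


class TestPCA:
    def test_two_dimensional_data_fully_explained(self):
        rng = np.random.default_rng(1)
        base = _toy_table(12)
        # build 9 features as exact linear combinations of two factors
        f1 = rng.standard_normal(12)
        f2 = rng.standard_normal(12)
        coefs = rng.standard_normal((9, 2))
        data = np.outer(f1, coefs[:, 0]) + np.outer(f2, coefs[:, 1])
        table = pd.DataFrame(data, columns=FEATURE_COLUMNS)
        res = standardize_and_pca2(table)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_feature_gets_equal_loadings(self):
        table = _toy_table(16)
        table["APD50_ms"] = table["APD90_ms"]  # exact duplicate after z-scoring
        res = standardize_and_pca2(table)
        l = res.loadings
        assert abs(l.loc["APD50_ms", "PC1"]) == pytest.approx(
            abs(l.loc["APD90_ms", "PC1"]), abs=1e-9
        )

    def test_sign_convention_apd90_positive_on_pc1(self):
        for seed in range(4):
            res = standardize_and_pca2(_toy_table(14, seed=seed))
            assert res.loadings.loc["APD90_ms", "PC1"] >= 0

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            standardize_and_pca2(_toy_table(4).head(2))

    def test_constant_feature_dropped_with_warning(self):
        table = _toy_table(10)
        table["Cm_pF"] = 45.0
        with pytest.warns(UserWarning, match="constant"):
            res = standardize_and_pca2(table)
        assert "Cm_pF" not in res.loadings.index


class TestKMeans:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.5, (20, 2))
        b = rng.normal(10, 0.5, (20, 2))
        labels = kmeans2(np.vstack([a, b]), seed=0)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((30, 2))
        np.testing.assert_array_equal(kmeans2(pts, seed=5), kmeans2(pts, seed=5))

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            kmeans2(np.ones((10, 2)), seed=0)
        with pytest.raises(ValueError):
            kmeans2(np.ones((1, 2)), seed=0)

    def test_cluster_semantics_by_apd90(self):
        table = _toy_table(20)
        res = cluster_cohort(table, seed=0)
        calls = res.phenotype_calls()
        assert set(res.label_semantics.values()) == {"atrial-like", "ventricular-like"}
        # the short-APD90 half must be the atrial-like cluster
        assert all(c == "atrial-like" for c in calls[:10])
        assert all(c == "ventricular-like" for c in calls[10:])


class TestROC:
    def test_perfect_separation(self):
        vals = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.8])
        labels = np.array([False, False, False, True, True, True])
        r = roc_youden(vals, labels)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 0.3 < r.cutoff < 0.6  # strictly between the groups
        assert r.direction == "greater"
        assert r.youden_J == pytest.approx(1.0)

    def test_identical_values_give_half_auc(self):
        r = roc_youden(np.ones(10), np.array([True, False] * 5))
        assert r.auc == 0.5

    def test_orientation_flips_for_inverted_feature(self):
        vals = np.array([0.8, 0.7, 0.6, 0.2, 0.1])
        labels = np.array([False, False, False, True, True])
        r = roc_youden(vals, labels)
        assert r.auc == 1.0 and r.direction == "less"

    def test_auc_matches_concordance_enumeration(self):
        """4-vs-4 toy with one overlapping pair: AUC equals the pairwise
        concordance count over 16 pairs."""
        pos = np.array([3.0, 5.0, 6.0, 7.0])
        neg = np.array([1.0, 2.0, 4.0, 3.5])
        vals = np.concatenate([neg, pos])
        labels = np.array([False] * 4 + [True] * 4)
        conc = sum(
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p, q in itertools.product(pos, neg)
        )
        r = roc_youden(vals, labels)
        assert r.auc == pytest.approx(conc / 16.0, abs=1e-12)

    def test_auc_equals_normalized_mannwhitney_u(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 15)
        b = rng.normal(1, 1, 12)
        vals = np.concatenate([a, b])
        labels = np.array([False] * 15 + [True] * 12)
        r = roc_youden(vals, labels)
        u = sps.mannwhitneyu(b, a, alternative="two-sided").statistic
        auc = u / (15 * 12)
        assert r.auc == pytest.approx(max(auc, 1 - auc), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1.0, 2.0], [True, True])


class TestCutoffClassifier:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.30, "atrial-like"),
            (0.44, "ventricular-like"),  # boundary is ventricular
            (0.43999, "atrial-like"),
            (0.9, "ventricular-like"),
        ],
    )
    def test_cutoff_semantics(self, ratio, expected):
        assert classify_by_cutoff(ratio) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_by_cutoff(float("nan"))


class TestMannWhitney:
    def test_full_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u in (0.0, 9.0)

    def test_identical_multisets(self):
        u, _ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n1*n2/2

    def test_exact_p_matches_enumeration(self):
        """n=3 vs 3: the exact two-sided p equals full enumeration of all
        C(6,3) rank assignments."""
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        u_obs, p = mann_whitney_u(a, b)
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        n1 = 3
        u_stats = []
        for idx in itertools.combinations(range(6), n1):
            r1 = ranks[list(idx)].sum()
            u1 = r1 - n1 * (n1 + 1) / 2
            u_stats.append(u1)
        u_stats = np.array(u_stats)
        u1_obs = ranks[:3].sum() - 6.0
        # two-sided: distance from the mean n1*n2/2
        d_obs = abs(u1_obs - 4.5)
        p_exact = np.mean(np.abs(u_stats - 4.5) >= d_obs - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestLevene:
    def test_location_shift_gives_zero(self):
        g1 = [1.0, 2.0, 5.0, 7.0, 8.0]
        g2 = [x + 100.0 for x in g1]
        w, p = levene_w([g1, g2])
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(11)
        g1 = rng.normal(0, 1, 30)
        g2 = rng.normal(0, 5, 30)
        w, p = levene_w([g1, g2])
        assert w > 0 and p < 0.05

    def test_matches_manual_formula(self):
        g1, g2 = [1.0, 2.0, 6.0], [2.0, 4.0, 12.0]
        w, _ = levene_w([g1, g2])
        z = [np.abs(np.array(g) - np.mean(g)) for g in (g1, g2)]
        zbars = [zi.mean() for zi in z]
        zall = np.concatenate(z).mean()
        n, k = 6, 2
        num = (n - k) * sum(3 * (zb - zall) ** 2 for zb in zbars)
        den = (k - 1) * sum(((zi - zb) ** 2).sum() for zi, zb in zip(z, zbars))
        assert w == pytest.approx(num / den, rel=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            levene_w([[1.0, 2.0]])
        with pytest.raises(ValueError):
            levene_w([[1.0], [2.0, 3.0]])


class TestEndToEnd:
    def test_synthetic_cohort_recovers_phenotypes(self, cohort_table):
        """PCA + k-means on the 46-cell cohort recovers the ground-truth
        phenotypes, the triangulation ratio is near-perfectly
        discriminating, and duration features dominate PC1."""
        from sklearn.metrics import adjusted_rand_score

        df = cohort_table
        res = cluster_cohort(df, seed=7)
        truth = (df["phenotype"] == "ventricular").to_numpy()
        calls = res.phenotype_calls() == "ventricular-like"
        assert adjusted_rand_score(truth, calls) >= 0.8
        r = roc_youden(df["APD20_APD90"].to_numpy(), truth)
        assert r.auc >= 0.9
        assert 0.2 < r.cutoff < 0.7
        pc1 = res.loadings["PC1"].abs()
        assert pc1[APD_FAMILY].min() > pc1.drop(APD_FAMILY).max()

    def test_enrichment_recovered_downstream(self):
        """Doubling the generated atrial fraction roughly doubles the
        atrial calls made by the unsupervised pipeline."""
        from dynaclamp.cell import generate_cohort
        from dynaclamp.pipeline import build_cohort_table

        fracs = {}
        for f in (0.3, 0.6):
            cells = generate_cohort(40, f, seed=21)
            tab = build_cohort_table(cells)
            tab = tab[tab["ok"]].reset_index(drop=True)
            res = cluster_cohort(tab, seed=21)
            calls = res.phenotype_calls()
            fracs[f] = np.mean(calls == "atrial-like")
        assert fracs[0.6] == pytest.approx(2 * fracs[0.3], abs=0.15)
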