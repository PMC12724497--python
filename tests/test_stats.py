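"""Rank statistics, effect sizes, FDR, regression and concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pathstrat.stats import (DegenerateDataError, RankDeficiencyError,
                             adjusted_regression, association_table, bh_fdr,
                             categorical_association, cliffs_delta,
                             concordance_permutation, cramers_v, eta_squared,
                             kruskal_eta2, spearman_with_ci, summarize_clusters)


def _spearman_bruteforce(x, y):
    """Pearson correlation of average ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman_with_ci([1, 2, 3, 4, 5], [10, 20, 30, 40, 50], B=50, seed=0)
        assert r.rho == pytest.approx(1.0)
        assert r.ci_low == pytest.approx(1.0)
        assert r.ci_high == pytest.approx(1.0)

    def test_perfect_antitone(self):
        r = spearman_with_ci([1, 2, 3, 4], [9, 7, 5, 3], B=50, seed=0)
        assert r.rho == -1.0

    def test_hand_ranked_example(self):
        x, y = [1, 2, 3, 4, 5], [1, 3, 2, 5, 4]
        r = spearman_with_ci(x, y, B=50, seed=0)
        assert r.rho == pytest.approx(_spearman_bruteforce(x, y))
        assert r.rho == pytest.approx(0.8)   # 1 - 6*4/(5*24)

    def test_bruteforce_agreement_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = spearman_with_ci(x, y, B=10, seed=0)
            assert r.rho == pytest.approx(_spearman_bruteforce(x, y), abs=1e-12)

    def test_normal_approx_p(self):
        r = spearman_with_ci([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5], B=10, seed=0)
        expected = 2 * sps.norm.sf(abs(r.rho) * np.sqrt(5))
        assert r.p == pytest.approx(expected)

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning):
            r = spearman_with_ci([1, 1, 1, 1], [1, 2, 3, 4], B=10, seed=0)
        assert np.isnan(r.rho)

    def test_too_few_observations(self):
        with pytest.raises(DegenerateDataError):
            spearman_with_ci([1, 2, 3], [1, 2, 3])


class TestBHFDR:
    def test_stepup_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_matches_bruteforce_on_permutations(self):
        base = np.array([0.001, 0.01, 0.04, 0.2, 0.5, 0.9])

        def stepup(p):
            m = len(p)
            order = np.argsort(p)
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out

        for perm in itertools.permutations(base):
            p = np.array(perm)
            assert np.allclose(bh_fdr(p), stepup(p), atol=1e-15)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(20)
        assert np.all(bh_fdr(p) >= p - 1e-15)


class TestKruskalEta2:
    @pytest.mark.parametrize("H,n,k,expected", [
        (167.15, 283, 5, 0.587),   # nigrostriatal
        (121.50, 277, 5, 0.432),   # frontostriatal
        (170.68, 270, 5, 0.629),   # sensory/visuospatial
        (165.25, 283, 5, 0.580),   # limbic
        (127.11, 283, 4, 0.445),   # microvascular (consistent with k=4)
    ])
    def test_eta2_identity_reproduces_reported_rows(self, H, n, k, expected):
        assert round(eta_squared(H, n, k), 3) == expected

    def test_zero_point(self):
        # H = k - 1 maps to eta2 = 0
        assert eta_squared(4.0, 100, 5) == pytest.approx(0.0)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=60)
        labels = rng.integers(0, 3, 60)
        res = kruskal_eta2(values, labels, variable="v")
        groups = [values[labels == g] for g in np.unique(labels)]
        H, p = sps.kruskal(*groups)
        assert res.H == pytest.approx(H)
        assert res.p == pytest.approx(sps.chi2.sf(H, 2))
        assert res.eta2 == pytest.approx((H - 2) / (60 - 3))

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 within [0.04, 0.06] (2000 sims)."""
        rng = np.random.default_rng(4)
        n, k, sims = 283, 5, 2000
        labels = np.repeat(np.arange(k), [57, 57, 57, 56, 56])
        rejections = 0
        for _ in range(sims):
            values = rng.standard_normal(n)
            if kruskal_eta2(values, labels).p < 0.05:
                rejections += 1
        assert 0.04 <= rejections / sims <= 0.06

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            kruskal_eta2([1.0, 2.0, 3.0], [0, 0, 0])


class TestCliffsDelta:
    def test_complete_separation(self):
        r = cliffs_delta([1, 2, 3], [4, 5, 6], B=50, seed=0)
        assert r.delta == -1.0

    def test_identical_multisets(self):
        r = cliffs_delta([1, 2, 2, 3], [1, 2, 2, 3], B=50, seed=0)
        assert r.delta == 0.0

    def test_hand_enumeration(self):
        r = cliffs_delta([1, 3], [2, 4], B=50, seed=0)
        assert r.delta == -0.5

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.integers(0, 6, rng.integers(1, 21)).astype(float)
            b = rng.integers(0, 6, rng.integers(1, 21)).astype(float)
            wins = sum(1 for x in a for y in b if x > y)
            losses = sum(1 for x in a for y in b if x < y)
            expected = (wins - losses) / (len(a) * len(b))
            assert cliffs_delta(a, b, B=2, seed=0).delta == pytest.approx(expected)

    def test_bounds_and_ci_order(self):
        rng = np.random.default_rng(6)
        r = cliffs_delta(rng.normal(0, 1, 30), rng.normal(1, 1, 25), B=200, seed=0)
        assert -1 <= r.ci_low <= r.delta <= r.ci_high <= 1


class TestCramersV:
    def test_perfect_association(self):
        assert cramers_v([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_independent_table(self):
        margins_r = np.array([12, 8])
        margins_c = np.array([5, 10, 5])
        table = np.outer(margins_r, margins_c) / 20
        assert cramers_v(table) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        assert cramers_v([[6, 4], [4, 6]]) == pytest.approx(0.2)

    def test_empty_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            cramers_v([[0, 0], [1, 2]])

    def test_fisher_for_sparse_2x2(self):
        out = categorical_association([[2, 1], [1, 3]])
        assert out["test"] == "fisher"
        out2 = categorical_association([[30, 20], [20, 30]])
        assert out2["test"] == "chi2"


class TestAdjustedRegression:
    def test_noiseless_slope_exact(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=80)
        y = 2.0 * x
        r = adjusted_regression(y, pd.Series(x, name="mpis"))
        assert r.beta == pytest.approx(2.0, abs=1e-10)
        assert r.p < 1e-20

    def test_null_coverage(self):
        """CI covers 0 for an orthogonal predictor in >= 94% of 500 runs."""
        rng = np.random.default_rng(8)
        covered = 0
        for _ in range(500):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            r = adjusted_regression(y, pd.Series(x, name="x"))
            covered += r.ci_low <= 0 <= r.ci_high
        assert covered / 500 >= 0.94

    def test_categorical_covariates_and_partial_r2(self):
        rng = np.random.default_rng(9)
        n = 120
        clusters = pd.get_dummies(rng.integers(0, 3, n), prefix="cl",
                                  drop_first=True, dtype=float)
        age = rng.normal(60, 8, n)
        y = 3.0 * clusters.iloc[:, 0] + 0.1 * age + rng.normal(size=n)
        cov = pd.DataFrame({"age": age, "sex": rng.choice(["M", "F"], n)})
        r = adjusted_regression(y, clusters, covariates=cov)
        assert 0 < r.partial_r2 < 1
        assert r.f_p < 1e-6

    def test_rank_deficiency_names_columns(self):
        n = 30
        x = np.arange(n, dtype=float)
        block = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RankDeficiencyError, match="collinear"):
            adjusted_regression(np.random.default_rng(0).normal(size=n), block)

    def test_constant_indicator_is_rank_deficient(self):
        n = 20
        block = pd.DataFrame({"cl": np.ones(n)})
        with pytest.raises(RankDeficiencyError):
            adjusted_regression(np.random.default_rng(1).normal(size=n), block)


class TestConcordance:
    def test_identical_labelings(self):
        labels = np.array([0, 1, 2] * 30)
        r = concordance_permutation(labels, labels, n_perm=99, seed=0)
        assert r.nmi == 1.0 and r.ari == 1.0
        assert r.perm_p_nmi == pytest.approx(1 / 100)
        assert r.perm_p_ari == pytest.approx(1 / 100)

    def test_relabeled_partition_still_perfect(self):
        a = np.array([0, 0, 1, 1, 2, 2] * 10)
        remap = {0: 5, 1: 9, 2: 0}
        b = np.array([remap[x] for x in a])
        r = concordance_permutation(a, b, n_perm=50, seed=0)
        assert r.nmi == 1.0 and r.ari == 1.0

    def test_independent_labels_not_significant(self):
        """Typical null behavior: median p over several independent draws
        is far from the significance threshold."""
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(5):
            a = rng.integers(0, 5, 300)
            b = rng.integers(0, 6, 300)
            r = concordance_permutation(a, b, n_perm=200, seed=1)
            ps.append(r.perm_p_ari)
        assert np.median(ps) > 0.05

    def test_p_never_zero(self):
        labels = np.array([0, 1] * 50)
        r = concordance_permutation(labels, labels, n_perm=1000, seed=2)
        assert r.perm_p_ari > 0 and r.perm_p_nmi > 0


class TestSummarizeClusters:
    @pytest.fixture()
    def clin(self):
        rng = np.random.default_rng(11)
        n = 90
        return pd.DataFrame({
            "diagnosis": rng.choice(["PD", "HC", "SWEDD"], n, p=[0.6, 0.25, 0.15]),
            "sex": rng.choice(["F", "M"], n),
            "medication_status": rng.choice(["on", "off"], n),
            "age": rng.normal(63, 8, n),
            "updrs3": rng.normal(20, 9, n),
            "moca": rng.normal(27, 2, n),
            "quip_sum": rng.normal(4.5, 1.7, n),
        })

    def test_single_cluster_equals_cohort_summary(self, clin):
        table = summarize_clusters(clin, np.zeros(len(clin), dtype=int))
        assert len(table) == 1
        assert table.iloc[0]["n"] == len(clin)
        assert table.iloc[0]["age_mean"] == pytest.approx(clin["age"].mean())

    def test_n_conservation(self, clin):
        labels = np.random.default_rng(12).integers(0, 4, len(clin))
        table = summarize_clusters(clin, labels)
        assert table["n"].sum() == len(clin)

    def test_known_per_cluster_means_recovered(self):
        rng = np.random.default_rng(13)
        labels = np.repeat([0, 1], 200)
        age = np.where(labels == 0, 55.0, 70.0) + rng.normal(0, 3, 400)
        clin = pd.DataFrame({"age": age, "diagnosis": ["PD"] * 400})
        table = summarize_clusters(clin, labels).set_index("cluster")
        se = 3 / np.sqrt(200)
        assert abs(table.loc[0, "age_mean"] - 55) < 4 * se
        assert abs(table.loc[1, "age_mean"] - 70) < 4 * se


def test_association_table_applies_one_fdr_family(small_cohort_std):
    fm, clinical, _ = small_cohort_std
    from pathstrat.pathways import assign_pathway_bins, compute_mpis
    from pathstrat.schema import default_bin_spec
    bins = assign_pathway_bins(fm.descriptors, default_bin_spec())
    scores = compute_mpis(fm, bins).scores
    table = association_table(scores, clinical.data, B=50, seed=0)
    assert len(table) == 18  # 6 pathways x 3 outcomes
    finite = table.dropna(subset=["p"])
    assert np.allclose(np.sort(finite["q"]), np.sort(bh_fdr(finite["p"])))
    assert (finite["q"] >= finite["p"] - 1e-12).all()
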