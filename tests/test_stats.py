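"""Inference: t-tests, FDR, rank correlations, demographics oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from neurofuse.stats import (
    bh_fdr,
    compare_groups,
    correlate_components_rois,
    correlate_gose,
    correlate_gose_rois,
    demographics,
    top_regions,
    voxelwise_group_ttest,
)


def bh_bruteforce(p):
    """Step-up definition: adj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def spearman_bruteforce(x, y):
    """Tie-corrected rank correlation = Pearson on average ranks."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestBhFdr:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_and_dominates_raw(self, ps):
        adj = bh_fdr(ps)
        np.testing.assert_allclose(adj, bh_bruteforce(ps), atol=1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_sorted_inputs_give_monotone_output(self):
        ps = np.sort(np.random.default_rng(0).uniform(size=20))
        assert np.all(np.diff(bh_fdr(ps)) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCompareGroups:
    def test_identical_groups_null(self):
        scores = pd.DataFrame({"IC1": [1.0, 2, 3, 1, 2, 3]})
        tab = compare_groups(scores, ["a"] * 3 + ["b"] * 3)
        assert tab.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc[0, "p"] == pytest.approx(1.0)

    def test_pooled_t_closed_form(self):
        # (1,2,3) vs (4,5,6): pooled sd 1, se sqrt(2/3), t = -3/se
        scores = pd.DataFrame({"IC1": [1.0, 2, 3, 4, 5, 6]})
        tab = compare_groups(scores, ["a"] * 3 + ["b"] * 3)
        assert tab.loc[0, "t"] == pytest.approx(-3.674, abs=5e-4)
        assert tab.loc[0, "ci_low"] <= tab.loc[0, "diff"] <= tab.loc[0, "ci_high"]

    def test_fdr_dominates_raw(self, rng):
        scores = pd.DataFrame(rng.normal(size=(30, 8)),
                              columns=[f"IC{i}" for i in range(8)])
        tab = compare_groups(scores, ["a"] * 15 + ["b"] * 15)
        assert (tab["p_fdr"] >= tab["p"] - 1e-15).all()

    def test_planted_effect_wins_smallest_p(self, rng):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            scores = pd.DataFrame(r.normal(size=(200, 10)),
                                  columns=[f"IC{i + 1}" for i in range(10)])
            labels = np.array(["a"] * 100 + ["b"] * 100)
            scores["IC4"] += (labels == "b") * 1.0
            tab = compare_groups(scores, labels)
            hits += tab.loc[tab["p"].idxmin(), "ic"] == "IC4"
        assert hits >= 19

    def test_degenerate_variance_flagged(self):
        scores = pd.DataFrame({"IC1": [1.0, 1, 1, 1]})
        tab = compare_groups(scores, ["a", "a", "b", "b"])
        assert bool(tab.loc[0, "degenerate"])


class TestSpearmanTables:
    def test_self_correlation_is_one(self, rng):
        scores = pd.DataFrame({"IC1": rng.normal(size=12)})
        tab = correlate_components_rois(scores, {"m": scores.rename(
            columns={"IC1": "roi01"})})
        assert tab.loc[0, "rho"] == pytest.approx(1.0)

    def test_monotone_maps(self):
        scores = pd.DataFrame({"IC1": [1.0, 2, 3, 4]})
        block = pd.DataFrame({"up": [10.0, 20, 30, 40],
                              "down": [40.0, 30, 20, 10]})
        tab = correlate_components_rois(scores, {"m": block})
        assert tab.set_index("roi").loc["up", "rho"] == pytest.approx(1.0)
        assert tab.set_index("roi").loc["down", "rho"] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle_with_ties(self, rng):
        y = rng.integers(1, 5, size=20).astype(float)  # heavy ties
        block = pd.DataFrame(
            {f"r{i}": rng.integers(0, 4, size=20).astype(float)
             for i in range(6)})
        tab = correlate_gose_rois({"m": block}, y)
        for _, row in tab.iterrows():
            expected = spearman_bruteforce(y, block[row["roi"]])
            assert row["rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_flagged(self):
        scores = pd.DataFrame({"IC1": [1.0, 2, 3, 4, 5]})
        block = pd.DataFrame({"r1": [2.0, 2, 2, 2, 2]})
        tab = correlate_components_rois(scores, {"m": block})
        assert bool(tab.loc[0, "degenerate"]) and np.isnan(tab.loc[0, "rho"])


class TestTopRegions:
    def test_largest_abs_first(self):
        tab = pd.DataFrame({
            "ic": "IC1", "modality": "m",
            "roi": ["a", "b", "c"], "rho": [0.5, -0.9, 0.3],
            "p": [0.1] * 3, "p_fdr": [0.2] * 3,
        })
        top = top_regions(tab, m=1)
        assert list(top["roi"]) == ["b"]

    def test_m_exceeding_rois_returns_all_sorted(self):
        tab = pd.DataFrame({
            "ic": "IC1", "modality": "m",
            "roi": ["a", "b"], "rho": [0.2, 0.8],
            "p": [0.5, 0.5], "p_fdr": [0.5, 0.5],
        })
        top = top_regions(tab, m=10)
        assert list(top["roi"]) == ["b", "a"]

    def test_matches_full_sort_oracle(self, rng):
        tab = pd.DataFrame({
            "ic": np.repeat(["IC1", "IC2"], 30),
            "modality": "m",
            "roi": [f"r{i:02d}" for i in range(30)] * 2,
            "rho": rng.uniform(-1, 1, 60),
        })
        tab["p"] = 0.5
        tab["p_fdr"] = 0.5
        top = top_regions(tab, m=5)
        for ic in ("IC1", "IC2"):
            sub = tab[tab["ic"] == ic]
            expected = sub.reindex(
                sub["rho"].abs().sort_values(ascending=False).index)
            got = top[top["ic"] == ic]
            assert list(got["roi"]) == list(expected["roi"].head(5))


class TestVoxelwise:
    def test_identical_groups_all_zero_t(self):
        maps = np.tile(np.arange(8.0).reshape(2, 2, 2), (6, 1, 1, 1))
        res = voxelwise_group_ttest(maps, np.ones((2, 2, 2), bool),
                                    ["a"] * 3 + ["b"] * 3)
        sel = ~res["degenerate"]
        np.testing.assert_allclose(res["t"][sel], 0.0)

    def test_agrees_with_per_voxel_compare_groups(self, rng):
        maps = rng.normal(size=(10, 3, 3, 1))
        labels = ["a"] * 5 + ["b"] * 5
        res = voxelwise_group_ttest(maps, np.ones((3, 3, 1), bool), labels)
        scores = pd.DataFrame(maps.reshape(10, -1),
                              columns=[f"v{i}" for i in range(9)])
        tab = compare_groups(scores, labels)
        np.testing.assert_allclose(res["t"].ravel(), tab["t"], atol=1e-12)
        np.testing.assert_allclose(res["p_fdr"].ravel(), tab["p_fdr"],
                                   atol=1e-12)

    def test_planted_shift_concentrates_significance(self, rng):
        grid = (6, 6, 2)
        region = np.zeros(grid, bool)
        region[:3, :3, :] = True
        base = 50.0 + rng.normal(0, 1.0, (80,) + grid)
        labels = np.array(["HC"] * 40 + ["mTBI"] * 40)
        base[40:][:, region] *= 1.10
        res = voxelwise_group_ttest(base, np.ones(grid, bool), labels)
        sig = res["p_fdr"] < 0.05
        assert sig[region].mean() >= 0.8
        assert sig[~region].mean() <= 0.2


class TestGose:
    def test_identity_scores_rho_one(self):
        gose = np.array([3.0, 5, 6, 7, 8])
        scores = pd.DataFrame({"IC1": gose})
        tab = correlate_gose(scores, gose)
        assert tab.loc[0, "rho"] == pytest.approx(1.0)

    def test_minimum_n_enforced(self):
        with pytest.raises(ValueError, match="n >= 5"):
            correlate_gose(pd.DataFrame({"IC1": [1.0, 2, 3]}), [4, 5, 6])

    def test_driving_source_attains_largest_rho(self, rng):
        from neurofuse.synthetic import synthesize_gose

        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            src = r.normal(size=40)
            gose = synthesize_gose(src).astype(float)
            scores = pd.DataFrame(r.normal(size=(40, 6)),
                                  columns=[f"IC{i + 1}" for i in range(6)])
            scores["IC3"] = src + 0.3 * r.normal(size=40)
            tab = correlate_gose(scores, gose)
            hits += tab.loc[tab["rho"].abs().idxmax(), "ic"] == "IC3"
        assert hits >= 18


class TestDemographics:
    @staticmethod
    def cohort(counts):
        (hf, hm), (tf, tm) = counts
        rows = (
            [{"group": "HC", "sex": "F", "age": 30.0}] * hf
            + [{"group": "HC", "sex": "M", "age": 29.0}] * hm
            + [{"group": "mTBI", "sex": "F", "age": 28.0}] * tf
            + [{"group": "mTBI", "sex": "M", "age": 27.0}] * tm
        )
        return pd.DataFrame(rows)

    def test_study_table_chi2(self):
        # 24 HC (12 F) vs 19 mTBI (10 F) -> X^2 = 0.029 without correction
        rep = demographics(self.cohort([(12, 12), (10, 9)]))
        assert round(rep["chi2"], 3) == 0.029
        assert rep["chi2_p"] == pytest.approx(0.864, abs=5e-4)

    def test_balanced_table_zero(self):
        rep = demographics(self.cohort([(10, 10), (10, 10)]))
        assert rep["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_definitional_formula(self, rng):
        for _ in range(10):
            counts = rng.integers(3, 30, size=4)
            tab = counts.reshape(2, 2)
            rep = demographics(self.cohort([tuple(tab[0]), tuple(tab[1])]))
            expected = sps.chi2_contingency(tab, correction=False)[0]
            # definitional sum over cells of (O-E)^2/E
            total = tab.sum()
            e = np.outer(tab.sum(1), tab.sum(0)) / total
            assert rep["chi2"] == pytest.approx(((tab - e) ** 2 / e).sum(),
                                                abs=1e-10)
            assert rep["chi2"] == pytest.approx(expected, abs=1e-10)

    def test_continuous_report_structure(self, rng):
        df = self.cohort([(5, 5), (4, 4)])
        df["age"] = rng.normal(30, 5, len(df))
        rep = demographics(df)
        age = rep["continuous"]["age"]
        assert {"shapiro", "ranksum_stat", "ranksum_p"} <= set(age)
        for w, p in age["shapiro"].values():
            assert 0 < w <= 1 and 0 <= p <= 1
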