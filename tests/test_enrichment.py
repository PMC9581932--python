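"""Rank scores, bounded annotation enrichment, BH and combined scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ploidyscale.enrichment import (
    AnnotationCatalog,
    AnnotationTerm,
    annotation_score_1d,
    bh_adjust,
    enrichment_2d,
    gsea_combined_scores,
    rank_scores,
)


def make_catalog(member_lists):
    return AnnotationCatalog.from_terms(
        AnnotationTerm(f"T{i}", f"term {i}", frozenset(m)) for i, m in enumerate(member_lists)
    )


class TestRankScores:
    def test_simple_and_ties(self):
        np.testing.assert_array_equal(rank_scores([0.1, 0.5, 0.3]), [1, 3, 2])
        np.testing.assert_array_equal(rank_scores([1.0, 1.0]), [1.5, 1.5])

    def test_missing_scores_stay_missing(self):
        r = rank_scores([0.2, np.nan, 0.1])
        assert np.isnan(r[1]) and list(r[[0, 2]]) == [2, 1]

    def test_matches_sort_based_oracle(self, rng):
        x = rng.normal(size=200)
        r = rank_scores(x)
        order = np.argsort(np.argsort(x)) + 1  # no ties almost surely
        np.testing.assert_array_equal(r, order)

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            rank_scores([np.nan, np.nan])


class TestAnnotationScore1d:
    def ranks(self, n):
        return pd.Series(np.arange(1, n + 1, dtype=float), index=[f"P{i}" for i in range(n)])

    def test_top_block_scores_plus_one(self):
        r = self.ranks(1000)
        top = [f"P{i}" for i in range(980, 1000)]
        assert annotation_score_1d(r, top) == pytest.approx(1.0)

    def test_bottom_block_scores_minus_one(self):
        r = self.ranks(1000)
        assert annotation_score_1d(r, [f"P{i}" for i in range(20)]) == pytest.approx(-1.0)

    def test_whole_universe_scores_zero(self):
        r = self.ranks(50)
        assert annotation_score_1d(r, list(r.index)) == 0.0

    def test_empty_intersection_is_unscored(self):
        assert annotation_score_1d(self.ranks(10), ["X1", "X2"]) is None

    def test_formula_oracle_and_null_mean(self, rng):
        r = self.ranks(200)
        means = []
        for _ in range(300):
            members = rng.choice(r.index, size=25, replace=False)
            s = annotation_score_1d(r, members)
            expected = 2 * (r[members].mean() - 201 / 2) / (200 - 25)
            assert s == pytest.approx(expected, abs=1e-12)
            means.append(s)
        assert abs(np.mean(means)) < 0.02

    def test_antisymmetric_under_rank_reversal(self, rng):
        r = self.ranks(100)
        rev = pd.Series(101 - r.to_numpy(), index=r.index)
        members = rng.choice(r.index, size=12, replace=False)
        assert annotation_score_1d(rev, members) == pytest.approx(
            -annotation_score_1d(r, members)
        )


class TestBhAdjust:
    def brute_force_bh(self, p):
        p = np.asarray(p, float)
        m = p.size
        q = np.empty(m)
        for i in range(m):
            cands = []
            for j in range(m):
                if p[j] >= p[i]:
                    rank_j = (p <= p[j]).sum()
                    cands.append(p[j] * m / rank_j)
            q[i] = min(1.0, min(cands))
        return q

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_tied(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_brute_force_step_up_oracle(self, rng):
        p = rng.random(50)
        np.testing.assert_allclose(bh_adjust(p), self.brute_force_bh(p), atol=1e-12)

    def test_monotone_and_idempotent(self, rng):
        p = np.sort(rng.random(30))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()
        np.testing.assert_allclose(bh_adjust(q), bh_adjust(bh_adjust(q)), atol=1e-12)

    def test_nan_propagates_and_bad_p_rejected(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[[0, 2]]).all()
        with pytest.raises(ValueError):
            bh_adjust([1.5])


def exhaustive_mannwhitney_p(x, y):
    """Enumerate all arrangements of the pooled values over the two groups."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs_u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    # two-sided p: probability of a U at least as extreme as observed
    u_vals = []
    for subset in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(subset)]
        ys = pooled[[i for i in range(len(pooled)) if i not in subset]]
        u_vals.append(stats.mannwhitneyu(xs, ys, alternative="two-sided").statistic)
    u_vals = np.array(u_vals)
    mu = n * len(y) / 2
    return float((np.abs(u_vals - mu) >= abs(obs_u - mu) - 1e-12).mean())


class TestEnrichment2d:
    def universe_ranks(self, n, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"P{i}" for i in range(n)]
        sx = pd.Series(rng.normal(size=n), index=ids)
        sy = pd.Series(rng.normal(size=n), index=ids)
        rx = pd.Series(rank_scores(sx), index=ids)
        ry = pd.Series(rank_scores(sy), index=ids)
        return rx, ry

    def test_mannwhitney_p_matches_exhaustive_enumeration(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(size=4) + 1.0
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        p_oracle = exhaustive_mannwhitney_p(x, y)
        assert p_scipy == pytest.approx(p_oracle, abs=1e-12)

    def test_planted_term_is_detected_in_both_dimensions(self):
        rng = np.random.default_rng(5)
        n = 400
        ids = [f"P{i}" for i in range(n)]
        score = pd.Series(rng.normal(size=n), index=ids)
        score[ids[:30]] += 5.0  # planted block at the top of both dimensions
        rx = pd.Series(rank_scores(score), index=ids)
        ry = pd.Series(rank_scores(score + rng.normal(0, 0.1, n)), index=ids)
        catalog = make_catalog([ids[:30]] + [rng.choice(ids, 20, replace=False) for _ in range(30)])
        out = enrichment_2d(rx, ry, catalog).set_index("term_id")
        assert out.loc["T0", "score_x"] > 0.8 and out.loc["T0", "score_y"] > 0.8
        assert out.loc["T0", "q_value"] < 0.02

    def test_null_catalog_false_positive_rate(self):
        flagged = total = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            rx, ry = self.universe_ranks(300, seed)
            catalog = make_catalog(
                [rng.choice(rx.index, 25, replace=False) for _ in range(150)]
            )
            out = enrichment_2d(rx, ry, catalog)
            flagged += int(out["significant"].sum())
            total += len(out)
        assert flagged / total <= 0.02 + 0.01

    def test_null_p_distribution_is_roughly_uniform(self):
        rng = np.random.default_rng(3)
        rx, ry = self.universe_ranks(300, 3)
        catalog = make_catalog([rng.choice(rx.index, 25, replace=False) for _ in range(500)])
        p = enrichment_2d(rx, ry, catalog)["p_value"].to_numpy()
        # min-p with Bonferroni doubling is conservative; allow one-sided slack
        ks = stats.kstest(p, "uniform")
        assert ks.statistic <= 0.1

    def test_mismatched_universes_rejected(self):
        rx, ry = self.universe_ranks(20)
        with pytest.raises(ValueError, match="universe"):
            enrichment_2d(rx, ry.iloc[:10], make_catalog([list(rx.index[:5])]))

    def test_small_terms_get_no_q(self):
        rx, ry = self.universe_ranks(50)
        out = enrichment_2d(rx, ry, make_catalog([list(rx.index[:3])]), min_members=10)
        assert np.isnan(out["q_value"]).all()


class TestGseaCombinedScores:
    def test_fisher_p_matches_scipy_fisher_exact(self):
        universe = [f"P{i}" for i in range(1000)]
        members = universe[:10]
        hits = set(universe[:8]) | set(universe[500:520])
        catalog = make_catalog([members])
        out = gsea_combined_scores(hits, catalog, universe, n_rank_permutations=5, seed=0)
        table = [[8, len(hits) - 8], [2, 1000 - len(hits) - 2]]
        ref = stats.fisher_exact(table, alternative="greater").pvalue
        assert out["fisher_p"][0] == pytest.approx(ref, rel=1e-10)

    def test_p_equal_one_gives_zero_score(self):
        universe = [f"P{i}" for i in range(50)]
        catalog = make_catalog([universe[:10], universe[10:30]])
        out = gsea_combined_scores(set(), catalog, universe, n_rank_permutations=5, seed=0)
        assert (out["fisher_p"] == 1.0).all()
        assert (out["combined_score"] == 0.0).all()

    def test_direction_down_flips_the_sign(self):
        rng = np.random.default_rng(2)
        universe = [f"P{i}" for i in range(300)]
        catalog = make_catalog(
            [universe[:25]] + [rng.choice(universe, 20, replace=False) for _ in range(20)]
        )
        hits = set(universe[:20]) | set(rng.choice(universe[25:], 10, replace=False))
        up = gsea_combined_scores(hits, catalog, universe, "up", 100, seed=9)
        down = gsea_combined_scores(hits, catalog, universe, "down", 100, seed=9)
        np.testing.assert_allclose(
            down["combined_score"], -up["combined_score"], atol=1e-12
        )
        assert up.loc[0, "combined_score"] > 0  # enriched term scores positive

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            gsea_combined_scores({"X"}, make_catalog([["P1"]]), ["P1", "P2"])
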