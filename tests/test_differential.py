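"""Moderated t, permutation FDR, trend fit and PDR classification."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ploidyscale.differential import (
    PloidyRegulationModel,
    TestConfig,
    classify_pdr,
    moderated_t,
    permutation_qvalues,
    protein_trend_fit,
    smoothness_flag,
)
from ploidyscale.differential import _combined_stat
from ploidyscale.preprocess import filter_valid_values, median_center
from ploidyscale.synthetic import SyntheticConfig, generate_proteome_dataset
from ploidyscale.tables_io import SCALE_LOG2

from conftest import make_matrix


class TestModeratedT:
    def test_identical_groups(self):
        t, p, fc = moderated_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == pytest.approx(1.0) and fc == 0

    def test_closed_form_student_oracle(self):
        """s0 = 0 reproduces the classical pooled-variance two-sample t."""
        a, b = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
        t, p, fc = moderated_t(a, b, s0=0.0)
        assert fc == pytest.approx(-2.0)
        assert t == pytest.approx(-np.sqrt(6), abs=1e-12)  # -2.449...
        assert p == pytest.approx(0.0705, abs=2e-4)
        # independent scipy cross-check
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_t_shrinks_monotonically_with_s0(self):
        a, b = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
        mags = [abs(moderated_t(a, b, s0=s)[0]) for s in (0.0, 0.5, 2.0, 50.0)]
        assert all(x > y for x, y in zip(mags, mags[1:]))
        assert mags[-1] < 0.05

    def test_small_groups_are_untestable_not_an_error(self):
        t, p, fc = moderated_t([1.0], [2.0, 3.0, 4.0])
        assert np.isnan(t) and np.isnan(p) and np.isnan(fc)


def exhaustive_q_oracle(X, n_a, s0=0.0):
    """Brute-force q values: enumerate all group-a index subsets, classical t,
    SAM-style FDR with a step-up envelope, all via independent scipy calls."""
    n_prot, n_tot = X.shape
    obs = np.array([
        stats.ttest_ind(X[i, :n_a], X[i, n_a:], equal_var=True).statistic
        for i in range(n_prot)
    ])
    perm = []
    for subset in itertools.combinations(range(n_tot), n_a):
        rest = [j for j in range(n_tot) if j not in subset]
        perm.append([
            abs(stats.ttest_ind(X[i, list(subset)], X[i, rest], equal_var=True).statistic)
            for i in range(n_prot)
        ])
    perm = np.array(perm)
    n_perm = perm.shape[0]
    obs_abs = np.abs(obs)
    fdr = np.empty(n_prot)
    for i in range(n_prot):
        thr = obs_abs[i]
        R = (obs_abs >= thr).sum()
        V = (perm >= thr).sum() / n_perm
        fdr[i] = min(V / R, 1.0)
    # step-up: q_i = min of fdr over proteins with |t| <= |t_i|
    q = np.array([fdr[obs_abs <= obs_abs[i]].min() for i in range(n_prot)])
    return q


class TestPermutationQvalues:
    def test_matches_exhaustive_enumeration_oracle(self, rng):
        """3-vs-3 instance: all 20 relabelings enumerated independently."""
        X = rng.normal(0, 1, size=(5, 6))
        X[0, :3] += 4.0
        matrix = make_matrix(X, ploidies=(1, 2), n_replicates=3, scale=SCALE_LOG2)
        q = permutation_qvalues(matrix, (2, 1), TestConfig(seed=1))
        oracle = exhaustive_q_oracle(X[:, [3, 4, 5, 0, 1, 2]], 3)
        np.testing.assert_allclose(q, oracle, atol=1e-12)

    def test_exhaustive_result_is_seed_independent(self, rng):
        X = rng.normal(0, 1, size=(8, 6))
        matrix = make_matrix(X, ploidies=(1, 2), n_replicates=3, scale=SCALE_LOG2)
        q1 = permutation_qvalues(matrix, (2, 1), TestConfig(seed=1))
        q2 = permutation_qvalues(matrix, (2, 1), TestConfig(seed=999))
        np.testing.assert_array_equal(q1, q2)

    def test_strongest_signal_has_minimal_q(self, rng):
        X = rng.normal(0, 0.05, size=(30, 6))
        X[7, 3:] += 4.0  # planted shift in the 2N group
        matrix = make_matrix(X, ploidies=(1, 2), n_replicates=3, scale=SCALE_LOG2)
        q = permutation_qvalues(matrix, (2, 1), TestConfig(seed=3))
        assert q[7] == np.nanmin(q)

    def test_qvalues_shrink_with_effect_size(self, rng):
        base = rng.normal(0, 0.3, size=(40, 6))
        qs = []
        for effect in (0.5, 2.0, 6.0):
            X = base.copy()
            X[5, 3:] += effect
            matrix = make_matrix(X, ploidies=(1, 2), n_replicates=3, scale=SCALE_LOG2)
            qs.append(permutation_qvalues(matrix, (2, 1), TestConfig(seed=3))[5])
        assert qs[0] >= qs[1] >= qs[2]

    def test_empty_group_cannot_be_permuted(self):
        matrix = make_matrix([[0.0, 1.0]], ploidies=(1, 2), n_replicates=1, scale=SCALE_LOG2)
        with pytest.raises(ValueError, match="relabel"):
            permutation_qvalues(matrix, (3, 1), TestConfig())


class TestCombinedStatistic:
    def test_euclidean_norm(self):
        assert _combined_stat(np.array([[3.0, 0.0, 4.0]]))[0] == pytest.approx(5.0)
        assert _combined_stat(np.array([[0.0, 0.0, 0.0]]))[0] == 0.0
        assert _combined_stat(np.array([[np.nan, np.nan, np.nan]]))[0] is not None
        assert np.isnan(_combined_stat(np.array([[np.nan, np.nan, np.nan]]))[0])

    def test_missing_pairs_use_available_ts(self):
        assert _combined_stat(np.array([[np.nan, 3.0, 4.0]]))[0] == pytest.approx(5.0)


class TestSmoothness:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((0, 0.6, 1.2, 1.9), True),
            ((0, 1.5, 1.6, 2.0), False),
            ((0, -0.9, -1.7, -2.2), True),
            ((0, np.nan, 0.8, 1.2), True),
            ((np.nan, np.nan, np.nan, np.nan), None),
            ((0.3,), None),
        ],
    )
    def test_rule(self, profile, expected):
        assert smoothness_flag(profile) is expected if expected is None else smoothness_flag(profile) == expected

    def test_invariant_to_additive_constant(self, rng):
        profile = rng.normal(0, 1, 4)
        assert smoothness_flag(profile) == smoothness_flag(profile + 13.7)


class TestProteinTrendFit:
    def test_perfect_line(self):
        slope, t, p, defined = protein_trend_fit([1.0, 2.0, 3.0, 4.0], [1, 2, 3, 4])
        assert defined and slope == pytest.approx(1.0)
        assert np.isinf(t) and p == 0.0

    def test_three_points_are_undefined(self):
        slope, t, p, defined = protein_trend_fit([1.0, 2.0, 3.0], [1, 2, 3])
        assert not defined and np.isnan(slope) and np.isnan(t) and np.isnan(p)

    def test_closed_form_ols_oracle(self, rng):
        x = np.array([1, 1, 2, 2, 3, 3, 4, 4], dtype=float)
        y = 0.7 * x + rng.normal(0, 0.5, x.size)
        slope, t, p, defined = protein_trend_fit(y, x)
        # independent closed-form OLS
        sxx = ((x - x.mean()) ** 2).sum()
        b = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - y.mean() - b * (x - x.mean())
        se = np.sqrt((resid**2).sum() / (x.size - 2) / sxx)
        assert defined
        assert slope == pytest.approx(b, rel=1e-12)
        assert t == pytest.approx(b / se, rel=1e-12)
        ref = stats.linregress(x, y)
        assert slope == pytest.approx(ref.slope)
        assert p == pytest.approx(ref.pvalue)

    def test_nan_points_do_not_count(self):
        slope, *_, defined = protein_trend_fit([1.0, np.nan, 3.0, 4.0], [1, 2, 3, 4])
        assert not defined


class TestClassifyPdr:
    def run_model(self, config=SyntheticConfig(n_proteins=300, seed=11), test=None):
        matrix, truth = generate_proteome_dataset(config)
        matrix, _ = filter_valid_values(matrix)
        centered = median_center(matrix.to_log2())
        results = PloidyRegulationModel(centered, test or TestConfig(seed=5)).fit()
        return results, truth

    def test_planted_smooth_up_proteins_recovered_as_consistent(self):
        """Up-PDR planted below the smooth-step bound land in consistent_up only."""
        config = SyntheticConfig(
            n_proteins=300, pdr_fraction=0.1, pdr_effect_log2_per_ploidy=0.9,
            noise_sd_log2=0.05, missing_rate_params=(-50.0, 0.0), seed=2,
        )
        results, truth = self.run_model(config, TestConfig(seed=5, fdr_threshold=0.1))
        sets = results.classify()
        up_planted = {p for p, b in zip(truth.protein_ids, truth.beta) if b > 0}
        down_planted = {p for p, b in zip(truth.protein_ids, truth.beta) if b < 0}
        assert up_planted <= set(sets.consistent_up)
        assert down_planted <= set(sets.consistent_down)
        assert not up_planted & set(sets.down)

    def test_jump_profiles_excluded_from_consistent_sets(self):
        config = SyntheticConfig(
            n_proteins=300, pdr_fraction=0.1, pdr_effect_log2_per_ploidy=0.9,
            noise_sd_log2=0.05, missing_rate_params=(-50.0, 0.0),
            jump_at_diploid=True, seed=2,
        )
        results, truth = self.run_model(config, TestConfig(seed=5, fdr_threshold=0.1))
        sets = results.classify()
        planted = set(truth.pdr_ids)
        # jump of 2.7 log2 units between 1N and 2N: significant but not smooth
        assert planted & (set(sets.up) | set(sets.down))
        assert not planted & (set(sets.consistent_up) | set(sets.consistent_down))

    def test_unreachable_fold_threshold_empties_sets(self):
        results, _ = self.run_model(test=TestConfig(seed=5, log2_fc_threshold=1e6))
        sets = results.classify()
        assert not sets.up and not sets.down

    def test_sets_ordered_by_descending_top_fold_change(self):
        config = SyntheticConfig(
            n_proteins=300, pdr_fraction=0.15, pdr_effect_log2_per_ploidy=0.8,
            noise_sd_log2=0.1, seed=4,
        )
        results, _ = self.run_model(config, TestConfig(seed=5, fdr_threshold=0.1))
        sets = results.classify()
        tab = results.table.set_index("protein_id")
        fc = tab["log2_fc_4N_1N"]
        for ids in (sets.up, sets.down):
            mags = [abs(fc[p]) for p in ids]
            assert mags == sorted(mags, reverse=True)

    def test_untestable_proteins_keep_their_rows(self):
        X = np.full((3, 12), 1.0)
        X[1, :] = np.nan
        X[1, 0] = 1.0  # one finite value in the 1N group only
        matrix = make_matrix(np.log2(np.exp2(X)), scale=SCALE_LOG2)
        results = PloidyRegulationModel(matrix, TestConfig(seed=0)).fit()
        assert len(results.table) == 3
        assert np.isnan(results.table.loc[1, "combined_stat"])
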