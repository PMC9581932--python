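"""Identification of ploidy-dependently regulated (PDR) proteins.

Input is a median-centered, log2-scale ratio matrix.  For each higher
ploidy versus the haploid baseline a pooled-variance two-sample t test is
computed with the SAM-style fudge constant ``s0`` added to the standard
error (``s0 = 0`` recovers the classical Student t).  False-discovery
control does not rely on the t reference distribution: q values come from
permutation of the sample labels, with the step-up envelope of the
estimated false-discovery fractions.

A combined cross-ploidy statistic — the Euclidean norm of the available
pairwise t statistics — summarises regulation across all ploidies, with its
own permutation null obtained by shuffling the sample-to-ploidy assignment
across all states.  Proteins are classified PDR when the combined q is
below the FDR threshold and the top-vs-haploid log2 fold change exceeds the
fold-change cutoff; the "consistent" subsets additionally require a smooth
profile (no consecutive-ploidy log2 step larger than ``smooth_max_step``).
A complementary per-protein linear trend ``ratio ~ ploidy`` (OLS, at least
four finite points) yields slope/t/p per protein.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import SCALE_LOG2, RatioMatrix


@dataclass(frozen=True)
class TestConfig:
    """Tuning constants of the PDR testing procedure.

    s0
        Fudge constant added to the two-sample standard error (t-statistic
        denominator units); 0 = classical Student t.
    n_permutations
        Random relabelings for the permutation FDR (exhaustive enumeration
        replaces sampling whenever the relabeling space is small enough).
    fdr_threshold
        q-value cutoff for calling a protein significant.
    log2_fc_threshold
        Minimum |log2 fold change| of the top-vs-haploid pair; 1 = 2-fold.
    smooth_max_step
        Largest tolerated |log2 FC| difference between consecutive ploidies.
    exhaustive_limit
        Enumerate all relabelings when their count is at most this.
    """

    __test__ = False  # config object, not a pytest case

    s0: float = 0.0
    n_permutations: int = 250
    fdr_threshold: float = 0.05
    log2_fc_threshold: float = 1.0
    smooth_max_step: float = 1.0
    seed: int | None = None
    exhaustive_limit: int = 10_000

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


# -- moderated t ----------------------------------------------------------


def moderated_t(group_a, group_b, s0: float = 0.0):
    """Pooled-variance two-sample t with fudge constant ``s0``.

    Returns ``(t_stat, p_value, log2_fc)`` with
    ``log2_fc = mean(a) - mean(b)`` and ``t = log2_fc / (s0 + se)``.  The p
    value is the two-sided Student t reference probability (FDR control is
    done by permutation, not by this p).  Groups with fewer than two finite
    values yield an untestable ``(nan, nan, nan)`` result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    t, p, fc = _ttest_arrays(a[None, :], b[None, :], s0)
    return float(t[0]), float(p[0]), float(fc[0])


def _ttest_arrays(A: np.ndarray, B: np.ndarray, s0: float):
    """Row-wise pooled-variance t for NaN-laden 2-D arrays.

    ``A`` is (n_proteins, n_a), ``B`` is (n_proteins, n_b).  Rows with fewer
    than 2 finite values in either group are NaN throughout.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        na = np.isfinite(A).sum(axis=1)
        nb = np.isfinite(B).sum(axis=1)
        ma = np.nanmean(A, axis=1)
        mb = np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1)
        vb = np.nanvar(B, axis=1, ddof=1)

    ok = (na >= 2) & (nb >= 2)
    na_s = np.where(ok, na, 2)
    nb_s = np.where(ok, nb, 2)
    df = na_s + nb_s - 2
    sp2 = ((na_s - 1) * np.where(ok, va, 0.0) + (nb_s - 1) * np.where(ok, vb, 0.0)) / df
    se = np.sqrt(sp2 * (1.0 / na_s + 1.0 / nb_s))
    fc = ma - mb
    denom = s0 + se
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / denom
    # zero spread and s0 == 0: t is 0 for a zero difference, +/-inf otherwise
    degenerate = denom == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(fc == 0, 0.0, np.sign(fc) * np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    t = np.where(ok, t, np.nan)
    p = np.where(ok, p, np.nan)
    fc = np.where(ok, fc, np.nan)
    return t, p, fc


# -- permutation FDR machinery --------------------------------------------


def _sam_qvalues(obs_abs: np.ndarray, perm_abs: np.ndarray, n_perm: int) -> np.ndarray:
    """Step-up permutation q values from observed and permuted |statistics|.

    For each observed |t| used as a threshold, the false-discovery fraction
    is estimated as (mean permuted count >= threshold) / (observed count >=
    threshold); the q value is the minimum of these estimates over all
    thresholds at or below the protein's own, capped at 1, so q is
    non-increasing in |t|.  NaN statistics (untestable rows) get NaN q.
    """
    q = np.full(obs_abs.shape, np.nan)
    finite = np.isfinite(obs_abs)
    vals = obs_abs[finite]
    if vals.size == 0:
        return q
    pool = perm_abs[np.isfinite(perm_abs)]
    pool.sort()

    order = np.argsort(-vals, kind="stable")  # strongest first
    sorted_vals = vals[order]
    asc = np.sort(vals)
    # observed count >= threshold (ties included)
    R = vals.size - np.searchsorted(asc, sorted_vals, side="left")
    V = (pool.size - np.searchsorted(pool, sorted_vals, side="left")) / float(n_perm)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = V / R
    fdr = np.minimum(fdr, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_vals = np.empty_like(q_sorted)
    q_vals[order] = q_sorted
    q[finite] = q_vals
    return q


def _pair_relabelings(
    n_total: int, n_a: int, config: TestConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index sets (positions assigned to group a) for two-group relabeling.

    Exhaustive (all C(n_total, n_a) subsets, seed-independent) when small
    enough, otherwise ``n_permutations`` uniform random subsets.
    """
    n_space = math.comb(n_total, n_a)
    if n_space < 2:
        raise ValueError("fewer than 2 distinct relabelings: nothing to permute")
    if n_space <= config.exhaustive_limit:
        return [np.array(c, dtype=int) for c in itertools.combinations(range(n_total), n_a)]
    return [rng.permutation(n_total)[:n_a] for _ in range(config.n_permutations)]


def permutation_qvalues(
    matrix: RatioMatrix,
    ploidy_pair: tuple[int, int],
    config: TestConfig = TestConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Permutation q values for one ploidy pair, aligned with the protein index.

    Samples of the two ploidies are relabeled (exhaustively when feasible),
    the full |t| vector recomputed per relabeling, and the step-up envelope
    of the estimated false-discovery fractions returned.
    """
    if matrix.scale != SCALE_LOG2:
        raise ValueError("permutation tests expect a median-centered log2 matrix")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pa, pb = ploidy_pair
    cols_a = matrix.samples_for_ploidy(pa)
    cols_b = matrix.samples_for_ploidy(pb)
    X = matrix.values[cols_a + cols_b].to_numpy(dtype=float)
    n_a = len(cols_a)

    t_obs, _, _ = _ttest_arrays(X[:, :n_a], X[:, n_a:], config.s0)
    labelings = _pair_relabelings(X.shape[1], n_a, config, rng)
    perm_abs = np.empty((len(labelings), X.shape[0]))
    all_idx = np.arange(X.shape[1])
    for k, idx_a in enumerate(labelings):
        idx_b = np.setdiff1d(all_idx, idx_a, assume_unique=False)
        t_perm, _, _ = _ttest_arrays(X[:, idx_a], X[:, idx_b], config.s0)
        perm_abs[k] = np.abs(t_perm)
    return _sam_qvalues(np.abs(t_obs), perm_abs, len(labelings))


def _combined_stat(t_matrix: np.ndarray) -> np.ndarray:
    """Euclidean norm of the available pairwise t statistics per protein."""
    finite = np.isfinite(t_matrix)
    any_pair = finite.any(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        norm = np.sqrt(np.nansum(t_matrix**2, axis=1))
    return np.where(any_pair, norm, np.nan)


def combined_ploidy_statistic(
    matrix: RatioMatrix,
    config: TestConfig = TestConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined cross-ploidy statistic and its permutation q values.

    The statistic is the Euclidean norm of the pairwise t statistics of each
    higher ploidy against the haploid baseline.  Its null is generated by
    shuffling the sample-to-ploidy assignment across all ploidy states and
    recomputing the norm, feeding the same step-up FDR estimator as the
    pairwise tests.
    """
    if matrix.scale != SCALE_LOG2:
        raise ValueError("permutation tests expect a median-centered log2 matrix")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ploidies = matrix.ploidies
    base = ploidies[0]
    group_cols = [matrix.samples_for_ploidy(p) for p in ploidies]
    sizes = [len(c) for c in group_cols]
    X = matrix.values[[c for cols in group_cols for c in cols]].to_numpy(dtype=float)
    bounds = np.cumsum([0] + sizes)

    def stat_for(order: np.ndarray) -> np.ndarray:
        blocks = [order[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
        ts = [
            _ttest_arrays(X[:, blocks[i]], X[:, blocks[0]], config.s0)[0]
            for i in range(1, len(sizes))
        ]
        return _combined_stat(np.column_stack(ts))

    identity = np.arange(X.shape[1])
    obs = stat_for(identity)
    perm = np.empty((config.n_permutations, X.shape[0]))
    for k in range(config.n_permutations):
        perm[k] = stat_for(rng.permutation(X.shape[1]))
    q = _sam_qvalues(obs, perm, config.n_permutations)
    return obs, q


# -- profile classification ----------------------------------------------


def smoothness_flag(profile, max_step: float = 1.0):
    """True iff no |log2 FC| step between consecutive defined ploidies exceeds ``max_step``.

    ``profile`` is the per-ploidy log2 fold-change profile in ploidy order
    (the haploid entry is 0 by construction).  Undefined (NaN) entries are
    skipped; with fewer than two defined entries the flag is undefined and
    ``None`` is returned.  Adding a constant to the whole profile does not
    change the flag.
    """
    arr = np.asarray(profile, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return None
    return bool(np.all(np.abs(np.diff(arr)) <= max_step))


def protein_trend_fit(values, ploidies):
    """Per-protein linear trend: OLS of ratio on ploidy.

    Requires at least four finite (value, ploidy) points; otherwise
    ``(nan, nan, nan, False)``.  Returns ``(slope, t, p, defined)`` with the
    two-sided p from the t distribution on n-2 degrees of freedom.  A
    perfect fit (zero residual variance) reports ``t = +/-inf, p = 0``.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(ploidies, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = y.size
    if n < 4 or np.ptp(x) == 0:
        return float("nan"), float("nan"), float("nan"), False
    sxx = float(np.sum((x - x.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    resid = y - (y.mean() + slope * (x - x.mean()))
    rss = float(np.sum(resid**2))
    if rss == 0.0:
        t = math.copysign(math.inf, slope) if slope != 0 else 0.0
        return slope, t, 0.0 if slope != 0 else 1.0, True
    se = math.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return slope, float(t), float(p), True


@dataclass(frozen=True)
class PdrSets:
    """PDR classification: significant up/down sets ordered by |top log2 FC| descending."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    consistent_up: tuple[str, ...]
    consistent_down: tuple[str, ...]

    def top(self, n: int = 25) -> dict[str, tuple[str, ...]]:
        """Heads of the consistent lists (heat-map style presentation)."""
        return {"up": self.consistent_up[:n], "down": self.consistent_down[:n]}


def classify_pdr(results: pd.DataFrame, config: TestConfig = TestConfig()) -> PdrSets:
    """Classify PDR proteins from a per-protein results table.

    A protein is up (down) when ``combined_q < fdr_threshold`` and its
    top-vs-haploid log2 FC is >= ``log2_fc_threshold`` (<= -threshold).
    The consistent subsets additionally require a smooth profile.  All sets
    are ordered by |top log2 FC| descending.
    """
    fc_col = results.attrs.get("top_fc_column")
    if fc_col is None:
        fc_cols = [c for c in results.columns if c.startswith("log2_fc_")]
        if not fc_cols:
            raise ValueError("results table has no log2_fc_* column")
        fc_col = fc_cols[-1]
    fc = results[fc_col]
    sig = (results["combined_q"] < config.fdr_threshold) & (
        fc.abs() >= config.log2_fc_threshold
    )
    smooth = results["is_smooth"].astype("boolean").fillna(False).astype(bool)

    def ordered(mask) -> tuple[str, ...]:
        sub = results.loc[mask].reindex(
            results.loc[mask, fc_col].abs().sort_values(ascending=False).index
        )
        return tuple(sub["protein_id"])

    up_mask = sig & (fc > 0)
    down_mask = sig & (fc < 0)
    return PdrSets(
        up=ordered(up_mask),
        down=ordered(down_mask),
        consistent_up=ordered(up_mask & smooth),
        consistent_down=ordered(down_mask & smooth),
    )


# -- model frontend -------------------------------------------------------


class PloidyRegulationModel:
    """PDR testing model over a median-centered log2 ratio matrix.

    ``fit()`` runs, for every ploidy above the haploid baseline: the
    moderated pairwise t test, its permutation q values, then the combined
    cross-ploidy statistic with its own permutation null, the smoothness
    flag and the per-protein linear trend.  Returns
    :class:`RegulationResults`.
    """

    def __init__(self, matrix: RatioMatrix, config: TestConfig = TestConfig()):
        if matrix.scale != SCALE_LOG2:
            raise ValueError("PloidyRegulationModel expects a log2-scale matrix")
        if len(matrix.ploidies) < 2:
            raise ValueError("need at least two ploidy states")
        self.matrix = matrix
        self.config = config

    def fit(self, rng: np.random.Generator | None = None) -> "RegulationResults":
        matrix, config = self.matrix, self.config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        ploidies = matrix.ploidies
        base = ploidies[0]
        base_cols = matrix.samples_for_ploidy(base)
        arr = matrix.values
        n = matrix.n_proteins

        table = pd.DataFrame({"protein_id": matrix.protein_ids})
        pair_names = []
        t_stack = []
        group_means = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for p in ploidies:
                group_means[p] = np.nanmean(
                    arr[matrix.samples_for_ploidy(p)].to_numpy(dtype=float), axis=1
                )
        for p in ploidies[1:]:
            cols = matrix.samples_for_ploidy(p)
            t, pval, fc = _ttest_arrays(
                arr[cols].to_numpy(dtype=float),
                arr[base_cols].to_numpy(dtype=float),
                config.s0,
            )
            q = permutation_qvalues(matrix, (p, base), config, rng)
            name = f"{p}N_{base}N"
            pair_names.append(name)
            t_stack.append(t)
            table[f"log2_fc_{name}"] = fc
            table[f"t_{name}"] = t
            table[f"p_{name}"] = pval
            table[f"q_{name}"] = q

        combined, combined_q = combined_ploidy_statistic(matrix, config, rng)
        table["combined_stat"] = combined
        table["combined_q"] = combined_q

        # profile relative to the haploid group mean; haploid entry is 0
        profile = np.column_stack(
            [group_means[p] - group_means[base] for p in ploidies]
        )
        table["is_smooth"] = [
            smoothness_flag(profile[i], config.smooth_max_step) for i in range(n)
        ]

        ploidy_per_sample = matrix.ploidy_of().to_numpy(dtype=float)
        values = arr.to_numpy(dtype=float)
        trend = [
            protein_trend_fit(values[i], ploidy_per_sample) for i in range(n)
        ]
        table["trend_slope"] = [t[0] for t in trend]
        table["trend_t"] = [t[1] for t in trend]
        table["trend_p"] = [t[2] for t in trend]
        table["trend_defined"] = [t[3] for t in trend]
        table.attrs["top_fc_column"] = f"log2_fc_{pair_names[-1]}"
        return RegulationResults(table, config, tuple(pair_names))


class RegulationResults:
    """Per-protein PDR test results with classification and summary views."""

    def __init__(self, table: pd.DataFrame, config: TestConfig, pairs: tuple[str, ...]):
        self.table = table
        self.config = config
        self.pairs = pairs

    def classify(self) -> PdrSets:
        return classify_pdr(self.table, self.config)

    def n_significant(self) -> int:
        sets = self.classify()
        return len(sets.up) + len(sets.down)

    def summary(self) -> str:
        sets = self.classify()
        tested = int(self.table["combined_q"].notna().sum())
        lines = [
            "Ploidy-dependent regulation (PDR) testing",
            f"  proteins            {len(self.table)} ({tested} testable)",
            f"  pairwise contrasts  {', '.join(self.pairs)}",
            f"  s0 = {self.config.s0}, permutations = {self.config.n_permutations}",
            f"  FDR < {self.config.fdr_threshold}, |log2 FC| >= {self.config.log2_fc_threshold}",
            f"  up   {len(sets.up)} (consistent {len(sets.consistent_up)})",
            f"  down {len(sets.down)} (consistent {len(sets.consistent_down)})",
        ]
        return "\n".join(lines)


def run_differential(
    matrix: RatioMatrix, config: TestConfig = TestConfig(), rng=None
) -> pd.DataFrame:
    """Functional wrapper: fit the regulation model and return the results table."""
    return PloidyRegulationModel(matrix, config).fit(rng=rng).table
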