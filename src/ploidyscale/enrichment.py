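"""Pathway-level statistics: rank-based annotation enrichment and a signed
Fisher x z combined score for ranked protein lists.

Two flavours are provided:

* **1D/2D annotation enrichment** — for each annotation term, the bounded
  score ``s = 2 (mean member rank - (N+1)/2) / (N - n)`` measures where the
  term's members sit in the ranking: +1 when they occupy the very top, -1
  at the bottom, 0 under random placement.  In two dimensions (here: 1N and
  4N regulation) each term gets a position in the score plane; significance
  is the smaller of the two per-dimension two-sided Mann-Whitney p values
  corrected for the dimension choice, with Benjamini-Hochberg control
  across terms.
* **combined-score ranked-list enrichment** — per term, a one-sided Fisher
  exact p for the overlap of a hit set with the term's members, and a
  z-score of how far the term's p-rank deviates from its expectation under
  random hit labels; the signed score ``-ln(p) * z`` is negated for the
  downregulated direction so both directions plot on one axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


@dataclass
class AnnotationCatalog:
    """Named annotation terms (GO/KEGG-like), each a set of protein ids."""

    terms: dict[str, AnnotationTerm]
    category: str = ""

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> AnnotationTerm:
        return self.terms[term_id]

    @classmethod
    def from_terms(cls, terms: Iterable[AnnotationTerm], category: str = "") -> "AnnotationCatalog":
        out: dict[str, AnnotationTerm] = {}
        for t in terms:
            if t.term_id in out:
                raise ValueError(f"duplicate term id {t.term_id!r}")
            out[t.term_id] = t
        return cls(out, category)

    @classmethod
    def from_gmt(cls, path, category: str = "") -> "AnnotationCatalog":
        """Read a GMT-like file: term <tab> description <tab> member ids."""
        terms = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                terms.append(AnnotationTerm(parts[0], parts[1], frozenset(parts[2:])))
        return cls.from_terms(terms, category)

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.terms.values():
                fh.write("\t".join([t.term_id, t.description, *sorted(t.members)]) + "\n")


# -- ranking and bounded scores -------------------------------------------


def rank_scores(scores) -> np.ndarray:
    """Ascending 1..N ranks with average ties; NaN scores stay NaN (excluded)."""
    arr = np.asarray(scores, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("all scores are missing; nothing to rank")
    ranks = np.full(arr.shape, np.nan)
    ranks[finite] = stats.rankdata(arr[finite], method="average")
    return ranks


def annotation_score_1d(ranks: Mapping[str, float] | pd.Series, member_ids) -> float | None:
    """Bounded enrichment score of a member set within a ranking.

    ``s = 2 (mean member rank - (N+1)/2) / (N - n)`` over the N finite
    ranks, n of which belong to members; s is +1 iff the members occupy the
    n largest ranks, -1 iff the n smallest, and 0 by convention when the
    members are the whole universe.  Returns None (unscored) for an empty
    intersection.
    """
    series = pd.Series(ranks, dtype=float)
    series = series[np.isfinite(series)]
    N = len(series)
    if N == 0:
        raise ValueError("no finite ranks")
    member_ranks = series[series.index.isin(set(member_ids))]
    n = len(member_ranks)
    if n == 0:
        return None
    if n == N:
        return 0.0
    s = 2.0 * (member_ranks.mean() - (N + 1) / 2.0) / (N - n)
    return float(s)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values; NaN p values propagate as NaN."""
    arr = np.asarray(p_values, dtype=float)
    finite = np.isfinite(arr)
    if ((arr[finite] < 0) | (arr[finite] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    q = np.full(arr.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(arr[finite], method="fdr_bh")[1]
    return q


# -- 2D enrichment ---------------------------------------------------------


def _dimension_pvalue(ranks: pd.Series, member_set: set) -> float:
    """Two-sided Mann-Whitney p comparing member vs non-member ranks."""
    is_member = ranks.index.isin(member_set)
    x = ranks[is_member].to_numpy()
    y = ranks[~is_member].to_numpy()
    if x.size == 0 or y.size == 0:
        return float("nan")
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def enrichment_2d(
    ranks_x,
    ranks_y,
    catalog: AnnotationCatalog,
    min_members: int = 10,
    q_threshold: float = 0.02,
) -> pd.DataFrame:
    """Two-dimensional annotation enrichment over a catalog.

    Both rankings must cover the same protein universe.  Per term the
    bounded score is computed in each dimension; the p value is the smaller
    of the two per-dimension two-sided Mann-Whitney p values, corrected for
    the choice of dimension via its exact null distribution
    ``1 - (1 - p_min)**2``.  Benjamini-Hochberg q values
    are computed across terms with at least ``min_members`` scored members;
    smaller terms keep NaN q.  ``significant`` marks q < ``q_threshold``.
    """
    rx = pd.Series(ranks_x, dtype=float).dropna()
    ry = pd.Series(ranks_y, dtype=float).dropna()
    if set(rx.index) != set(ry.index):
        raise ValueError("the two dimensions rank different protein universes")
    ry = ry[rx.index]

    rows = []
    for term in catalog:
        members = set(term.members) & set(rx.index)
        n = len(members)
        if n == 0:
            rows.append((term.term_id, 0, np.nan, np.nan, np.nan))
            continue
        sx = annotation_score_1d(rx, members)
        sy = annotation_score_1d(ry, members)
        px = _dimension_pvalue(rx, members)
        py = _dimension_pvalue(ry, members)
        # exact null distribution of the smaller of two independent p values;
        # uniform under independence, conservative under positive dependence
        pmin = float(np.nanmin([px, py]))
        p = 1.0 - (1.0 - pmin) ** 2
        rows.append((term.term_id, n, sx, sy, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "n_members_scored", "score_x", "score_y", "p_value"]
    )
    eligible = out["n_members_scored"] >= min_members
    q = np.full(len(out), np.nan)
    if eligible.any():
        q[eligible.to_numpy()] = bh_adjust(out.loc[eligible, "p_value"].to_numpy())
    out["q_value"] = q
    out["significant"] = out["q_value"] < q_threshold
    return out


# -- combined-score ranked-list enrichment --------------------------------


def _fisher_p(n_overlap: int, n_hits: int, n_members: int, n_universe: int) -> float:
    """One-sided Fisher exact (enrichment) p = hypergeometric upper tail."""
    if n_hits == 0 or n_members == 0 or n_hits == n_universe or n_members == n_universe:
        return 1.0
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_members, n_hits))


def gsea_combined_scores(
    hit_set,
    catalog: AnnotationCatalog,
    universe,
    direction: str = "up",
    n_rank_permutations: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Signed combined enrichment scores for a hit set over a term catalog.

    Per term: a one-sided Fisher exact p for the 2x2 hit x membership
    table, and a z-score of rank deviation — how far the term's observed
    rank (of its Fisher p among all terms, ascending, average ties) falls
    below its expected rank under ``n_rank_permutations`` random hit sets of
    the same size.  ``combined_score = -ln(fisher_p) * z``; for
    ``direction="down"`` the sign is flipped so both directions share one
    axis.  Degenerate tables give p = 1, z = 0, score 0.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    universe = sorted(set(universe))
    hits = set(hit_set)
    if not hits <= set(universe):
        raise ValueError("hit_set must be a subset of the universe")
    rng = np.random.default_rng(seed)
    n_u = len(universe)
    n_h = len(hits)
    terms = list(catalog)
    member_sets = [set(t.members) & set(universe) for t in terms]
    n_m = np.array([len(m) for m in member_sets])

    def pvec(hit_ids: set) -> np.ndarray:
        overlaps = np.array([len(hit_ids & m) for m in member_sets])
        return np.array(
            [
                _fisher_p(o, len(hit_ids), k, n_u)
                for o, k in zip(overlaps, n_m)
            ]
        )

    obs_p = pvec(hits)
    obs_rank = stats.rankdata(obs_p, method="average")

    perm_ranks = np.empty((n_rank_permutations, len(terms)))
    uni_arr = np.array(universe)
    for k in range(n_rank_permutations):
        fake = set(rng.choice(uni_arr, size=n_h, replace=False)) if n_h else set()
        perm_ranks[k] = stats.rankdata(pvec(fake), method="average")
    exp_rank = perm_ranks.mean(axis=0)
    sd_rank = perm_ranks.std(axis=0, ddof=1) if n_rank_permutations > 1 else np.zeros(len(terms))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (exp_rank - obs_rank) / sd_rank
    z = np.where(~np.isfinite(z), 0.0, z)
    z = np.where(obs_p >= 1.0, 0.0, z)

    with np.errstate(divide="ignore"):
        combined = -np.log(obs_p) * z
    combined = np.where(obs_p >= 1.0, 0.0, combined)
    if direction == "down":
        combined = -combined

    overlaps = np.array([len(hits & m) for m in member_sets])
    return pd.DataFrame(
        {
            "term_id": [t.term_id for t in terms],
            "overlap": overlaps,
            "fisher_p": obs_p,
            "z_rank_deviation": z,
            "combined_score": combined,
            "direction": direction,
        }
    )
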