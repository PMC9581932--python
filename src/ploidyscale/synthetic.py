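"""Synthetic spike-in SILAC datasets with known ground truth.

The generator emulates the study design every downstream stage expects: an
isogenic ploidy series (1N-4N by default, three replicates each) measured
against a heavy-labeled standard that is an equal mix of all ploidy states.
The generative model for protein *i* at ploidy *N* is

    amount_i(N) = c_i * N**b * 2**(beta_i * (N - 1))

with lognormal baselines ``c_i``, a single global allometric exponent *b*,
and a planted per-protein log2-linear trend ``beta_i`` that is non-zero for
a small ploidy-dependently regulated (PDR) subset.  The heavy standard is
the equal mix of the noise-free per-ploidy amounts (one physical pool
measured in every sample); the reported light/heavy ratio per sample adds
lognormal measurement noise and is masked missing with an
intensity-dependent logistic probability, so low-abundance proteins drop
out more often — mimicking the detectability pattern of real runs.

Everything is reproducible from (config, seed), and matching annotation and
transcriptome fixtures with recorded truth are generated here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .enrichment import AnnotationCatalog, AnnotationTerm
from .tables_io import SCALE_LINEAR, RatioMatrix, SampleMeta
from .transcriptome import TranscriptMatrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings of the spike-in SILAC simulation.

    Defaults describe the emulated study conditions: ~3000 quantified
    proteins across a 1N-4N series in triplicate, a global exponent of
    0.78, a small (2%) PDR subset moving 1 log2 unit per ploidy step, and
    replicate scatter of 0.2 log2 units.
    """

    n_proteins: int = 3000
    ploidies: tuple[int, ...] = (1, 2, 3, 4)
    n_replicates: int = 3
    true_exponent_b: float = 0.78
    pdr_fraction: float = 0.02
    pdr_effect_log2_per_ploidy: float = 1.0
    noise_sd_log2: float = 0.2
    #: (intercept, slope) of the logistic missingness model on log2 amount;
    #: the negative slope makes low-abundance measurements drop out more.
    missing_rate_params: tuple[float, float] = (-3.0, -0.4)
    baseline_log2_sd: float = 2.0
    jump_at_diploid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.pdr_fraction < 1:
            raise ValueError("pdr_fraction must lie in [0, 1)")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if any(int(p) < 1 for p in self.ploidies) or len(set(self.ploidies)) != len(self.ploidies):
            raise ValueError("ploidies must be distinct positive integers")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset: baselines, planted trends, config."""

    protein_ids: list[str]
    baselines: np.ndarray  # c_i, linear abundance units
    beta: np.ndarray  # planted log2 trend per ploidy step (0 for non-PDR)
    is_pdr: np.ndarray  # boolean
    config: SyntheticConfig

    @property
    def pdr_ids(self) -> list[str]:
        return [pid for pid, f in zip(self.protein_ids, self.is_pdr) if f]


def _sample_grid(config: SyntheticConfig) -> list[SampleMeta]:
    return [
        SampleMeta(f"{p}N_r{r}", int(p), r)
        for p in config.ploidies
        for r in range(1, config.n_replicates + 1)
    ]


def generate_proteome_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[RatioMatrix, SyntheticTruth]:
    """Simulate a spike-in SILAC ratio matrix plus its ground truth.

    With zero noise, no PDR and no missingness the anchored per-ploidy
    medians are exactly ``N**b``.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ploidies = np.array(config.ploidies, dtype=float)

    baselines = np.exp2(rng.normal(0.0, config.baseline_log2_sd, size=n))
    is_pdr = rng.random(n) < config.pdr_fraction
    signs = rng.choice([-1.0, 1.0], size=n)
    beta = np.where(is_pdr, signs * config.pdr_effect_log2_per_ploidy, 0.0)

    # noise-free per-cell amounts, proteins x ploidies
    if config.jump_at_diploid:
        # whole planted effect lands between 1N and 2N, flat afterwards
        total = beta * (ploidies.max() - ploidies.min())
        reg = np.exp2(np.outer(total, (ploidies > ploidies.min()).astype(float)))
    else:
        reg = np.exp2(np.outer(beta, ploidies - 1.0))
    amounts = baselines[:, None] * ploidies[None, :] ** config.true_exponent_b * reg
    heavy = amounts.mean(axis=1)  # the equal-mix standard pool

    samples = _sample_grid(config)
    protein_ids = [f"P{i:05d}" for i in range(n)]
    values = np.empty((n, len(samples)))
    intercept, slope = config.missing_rate_params
    for j, s in enumerate(samples):
        k = list(config.ploidies).index(s.ploidy)
        noise = rng.normal(0.0, config.noise_sd_log2, size=n)
        values[:, j] = amounts[:, k] / heavy * np.exp2(noise)
        p_missing = expit(intercept + slope * np.log2(amounts[:, k]))
        values[rng.random(n) < p_missing, j] = np.nan

    matrix = RatioMatrix(
        values=pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                            columns=[s.sample_id for s in samples]),
        samples=samples,
        scale=SCALE_LINEAR,
    )
    truth = SyntheticTruth(protein_ids, baselines, beta, is_pdr, config)
    return matrix, truth


def generate_annotation_catalog(
    n_terms: int,
    size_range: tuple[int, int],
    enriched_terms: list[tuple[str, float]],
    truth: SyntheticTruth,
    seed: int | None = None,
    scores: np.ndarray | None = None,
) -> AnnotationCatalog:
    """Random annotation catalog with optional planted enrichment.

    Unlisted terms draw members uniformly; a term listed in
    ``enriched_terms`` with shift *g* draws members with probability
    weights ``exp(g * zscore(score))`` (exponential tilting), so positive
    shifts preferentially recruit high-score proteins and the term's
    expected enrichment sign is known.  ``scores`` defaults to the planted
    per-protein trend ``truth.beta``.
    """
    lo, hi = size_range
    if hi > len(truth.protein_ids):
        raise ValueError("term sizes cannot exceed the number of proteins")
    rng = np.random.default_rng(seed)
    score = np.asarray(truth.beta if scores is None else scores, dtype=float)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    ids = np.array(truth.protein_ids)
    shifts = dict(enriched_terms)
    if len(shifts) != len(enriched_terms):
        raise ValueError("enriched term names must be unique")

    # enriched names occupy the head of the catalog; the rest are generic
    names = list(shifts)
    if len(names) > n_terms:
        raise ValueError("more enriched terms than n_terms")
    k = 0
    while len(names) < n_terms:
        cand = f"TERM{k:04d}"
        if cand not in shifts:
            names.append(cand)
        k += 1

    terms = []
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        g = shifts.get(name, 0.0)
        if g == 0.0:
            members = rng.choice(ids, size=size, replace=False)
        else:
            w = np.exp(g * z)
            w = w / w.sum()
            members = rng.choice(ids, size=size, replace=False, p=w)
        terms.append(AnnotationTerm(name, f"synthetic term {name}", frozenset(map(str, members))))
    return AnnotationCatalog.from_terms(terms, category="synthetic")


@dataclass
class TranscriptomeTruth:
    """Ground truth of a simulated spike-in transcriptome."""

    capture_factors: pd.Series  # per-sample multiplicative capture efficiency
    changed_genes: dict[str, float]  # gene id -> fold at the highest ploidy
    seed: int | None


def generate_transcriptome_dataset(
    n_genes: int,
    n_spike: int,
    ploidies: tuple[int, ...] = (1, 2, 3, 4),
    fold_profile: dict[int, float] | None = None,
    noise_sd_log2: float = 0.0,
    seed: int | None = None,
    n_replicates: int = 1,
) -> tuple[TranscriptMatrix, TranscriptomeTruth]:
    """Simulate spike-in transcript intensities with planted fold changes.

    Every sample gets a random capture factor multiplying all of its rows
    (spike-in rows included).  Sample genes listed in ``fold_profile``
    (gene index -> fold at the highest ploidy) additionally follow a
    log-linear fold trajectory across ploidies; all other genes are flat.
    With zero noise, rescaling to the spike-in standard recovers the
    capture factors exactly.
    """
    if n_spike < 1:
        raise ValueError("need at least one spike-in gene")
    rng = np.random.default_rng(seed)
    fold_profile = fold_profile or {}
    ploidy_arr = np.array(sorted(ploidies), dtype=float)
    span = ploidy_arr.max() - ploidy_arr.min()

    samples = [
        SampleMeta(f"{int(p)}N_r{r}", int(p), r)
        for p in ploidy_arr
        for r in range(1, n_replicates + 1)
    ]
    gene_ids = [f"G{i:05d}" for i in range(n_genes)] + [f"SPIKE{i:03d}" for i in range(n_spike)]
    spike = pd.Series([False] * n_genes + [True] * n_spike,
                      index=pd.Index(gene_ids, name="gene_id"))

    base = np.exp2(rng.normal(10.0, 2.0, size=n_genes + n_spike))
    capture = pd.Series(
        np.exp2(rng.normal(0.0, 0.5, size=len(samples))),
        index=[s.sample_id for s in samples], name="capture",
    )

    fold = np.ones((n_genes + n_spike, len(samples)))
    for gi, f in fold_profile.items():
        if not 0 <= gi < n_genes:
            raise ValueError(f"fold_profile index {gi} is not a sample gene")
        for j, s in enumerate(samples):
            frac = (s.ploidy - ploidy_arr.min()) / span if span else 0.0
            fold[gi, j] = f ** frac

    noise = np.exp2(rng.normal(0.0, noise_sd_log2, size=fold.shape))
    intensities = base[:, None] * fold * capture.to_numpy()[None, :] * noise
    matrix = TranscriptMatrix(
        intensities=pd.DataFrame(intensities, index=spike.index,
                                 columns=[s.sample_id for s in samples]),
        samples=samples,
        spike=spike,
    )
    truth = TranscriptomeTruth(
        capture_factors=capture,
        changed_genes={gene_ids[gi]: f for gi, f in fold_profile.items()},
        seed=seed,
    )
    return matrix, truth
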