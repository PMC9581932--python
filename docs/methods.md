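# Methods

## The measurement model

The pipeline starts from spike-in SILAC light/heavy (L/H) ratio tables:
one value per protein group and sample, where the heavy channel is a
common standard pool (an equal protein mix of all ploidy states) added to
every sample.  Because the standard is the same physical pool everywhere,
L/H ratios are comparable across samples up to per-sample loading factors.
The study design is a 1N–4N isogenic ploidy series in triplicate, but the
code accepts any set of distinct positive ploidies and any replicate
count.

Two normalisations serve the two analysis branches and are deliberately
kept separate:

* **Haploid anchoring** (scaling branch, linear scale): all 1N values are
  pooled into one distribution and the single factor `1/median` is applied
  to every value of every sample, so the 1N median becomes exactly 1 and
  every between-sample ratio is untouched.  Pooling all 1N samples rather
  than averaging per-sample medians treats the haploid ratios as one
  distribution shifted to center at 1; the two choices differ only when
  replicate medians disagree.
* **Per-sample median centering** (differential branch, log2 scale): each
  sample column is shifted additively to median 0.  Centering per sample
  rather than per ploidy group is the stricter choice: it also removes
  replicate-level loading bias, at the cost of absorbing any genuine
  global shift shared by *most* proteins of a ploidy — which is exactly
  what the scaling branch is for.  This is why the differential branch
  detects *deviations from* the global trend, not the trend itself.

Filtering follows the spike-in design: a protein is kept when at least
`min_valid = 2` of the replicates of at least one ploidy are quantified.
The alternative reading "more than two" (= 3) is available via
configuration.  No imputation is performed anywhere.

## Allometric scaling fit

The global trend is `amount = a · N^b`, fitted by OLS of `ln(median)` on
`ln(ploidy)`.  The default estimates a free intercept (`ln a`), the
spreadsheet "power trendline" convention; a through-origin variant
(`a = 1`, natural for anchored data) is available but yields a visibly
different exponent on the same medians — on the packaged median series the
free-intercept fit gives b = 0.78, through-origin 0.77.  R² is reported on
the log–log scale (the scale on which the model is linear); it is clamped
to [0, 1] so the through-origin variant cannot report a negative value.
The per-ploidy medians are the default fit input; per-protein power fits
(the same estimator applied row-wise to each protein's per-ploidy mean
profile) are offered as an auxiliary view of the exponent distribution.

Geometric null expectations: if volume scales `v`-fold, an isometric
d-dimensional quantity scales `v^(d/3)`-fold (d = 1 length, 2 surface,
3 volume).  These are the comparison points for interpreting b — e.g.
proteome scaling between the surface law (2/3) and the metabolic 3/4.

## PDR testing

**Moderated t.**  For each higher ploidy versus 1N,
`t = (mean_a − mean_b)/(s0 + SE)` with the pooled-variance two-sample
standard error, degrees of freedom `n_a + n_b − 2`, and the SAM-style
fudge constant `s0` (default 0, recovering the classical Student t;
pooled variance, not Welch, matching the classical test).  Groups with
fewer than two finite values make a protein untestable for that pair —
the row is kept with missing statistics so output rows always align with
input rows.  With zero spread and `s0 = 0`, t is 0 for a zero difference
and ±∞ otherwise (p = 0), a documented convention rather than an error.

**Permutation FDR.**  The parametric p values are reference values only;
error control comes from relabeling.  For a pairwise test, group labels
are reassigned over the pooled samples — exhaustively (all `C(n, n_a)`
subsets, seed-independent) when that space has at most 10,000 elements,
otherwise by `n_permutations = 250` uniform random subsets.  For each
threshold equal to an observed |t|, the false-discovery fraction is
estimated as (mean permuted count ≥ threshold)/(observed count ≥
threshold); the q value is the step-up envelope — the minimum of these
estimates over all thresholds at or below the protein's own — capped
at 1.  No null-proportion (π₀) rescaling is applied; with at most a few
percent of truly regulated proteins the factor is ≈ 1 and omitting it is
(slightly) conservative.

**Combined statistic.**  The cross-ploidy summary is the Euclidean norm
of the available pairwise t statistics, chosen for symmetry and sign-free
magnitude; its null is generated by shuffling the sample-to-ploidy
assignment across *all* states and recomputing the norm, so the choice of
combination function needs no parametric calibration.  With `s0 = 0` and
triplicates, the pairwise null is t(4)-distributed and heavy-tailed, so
small-variance null proteins occasionally produce large norms; the
fold-change filter (below) is what removes these in classification.

**Classification.**  A protein is up/down-PDR when its combined q is
below the FDR threshold (default 0.05) *and* its top-vs-haploid log2 fold
change is at least 1 (2-fold) in magnitude; the "consistent" subsets
additionally require a smooth profile — no |log2 FC| step between
consecutive quantified ploidies above 1.  All sets are ordered by |top
fold change| descending, so heat-map-style "top 25" lists are simply the
heads of these lists.  Note an interaction worth knowing: a planted trend
of exactly 1 log2/step sits on the smoothness boundary, so measurement
noise randomises its flag; smoothness is a profile-shape statement, not a
significance statement.

**Linear trend.**  Complementarily, each protein's median-centered log2
ratios are regressed on ploidy (intercept + slope).  At least four finite
points are required, else all trend fields are reported missing; a
perfect fit reports t = ±∞, p = 0.

## Pathway statistics

The bounded 1D score of a term with n of N ranked proteins is
`s = 2(mean member rank − (N+1)/2)/(N − n)`: +1 when the members occupy
the top n ranks, −1 at the bottom, 0 by convention when the term is the
whole universe.  The 2D analysis (1N vs 4N regulation) scores each term
in both dimensions; significance per dimension is a two-sided
Mann–Whitney test of member versus non-member ranks, combined across the
two dimensions via the exact null of the smaller p value,
`1 − (1 − p_min)²` — uniform under independence and conservative under
the positive dependence typical of the two dimensions.  (Plain Bonferroni
doubling was rejected because its null p distribution deviates from
uniform by 0.25 in Kolmogorov distance, defeating calibration checks.)
Benjamini–Hochberg control is applied over terms with at least 10 scored
members (smaller terms are scored but not tested); the default
significance threshold is q < 0.02.

The ranked-list combined score per term is `−ln(p_Fisher) · z`, the
published EnrichR form, where `p_Fisher` is the one-sided
(hypergeometric-tail) Fisher exact p of the hit×membership 2×2 table and
z measures how far the term's p-rank falls below its expectation under
random hit sets of the same size (mean/SD over 200 label shuffles).
Down-direction scores are negated so both directions share one axis.
Degenerate tables give p = 1, z = 0, score 0.  The z-score is defined by
the term's rank *among all terms*, so the natural unit of computation is
the catalog, not a single term.

## Synthetic data

The generator mirrors the design end to end.  Per protein i at ploidy N
the true per-cell amount is `c_i · N^b · 2^{β_i (N−1)}` with lognormal
baselines (log2 sd 2, a proteome-like dynamic range) and a planted log2-
linear trend β_i, non-zero (±1 log2/step) for a Bernoulli-sampled PDR
subset (default 2%).  The heavy standard is the equal mix of the
*noise-free* per-ploidy amounts — one physical pool measured everywhere.
Reported ratios multiply the true ratio by `2^ε`, ε ~ N(0, 0.2) log2
units per measurement; the noise magnitude is a free parameter chosen for
plausible replicate scatter, as no measured value is available.  Each
measurement is masked missing with probability
`logistic(−3 − 0.4·log2 amount)`, making low-abundance proteins drop out
more often (≈ 5% missingness at baseline amounts, rising steeply below);
missingness depends on the noise-free amount, which keeps the
monotonicity property exact.  A "jump at diploid" variant concentrates
the whole planted effect between 1N and 2N to exercise the smoothness
filter.  All outputs are bit-reproducible from (config, seed), and the
generator writes the same TSV dialect the parser reads, so synthetic runs
exercise the full I/O path.

What the generator does *not* emulate: peptide-level effects, shared
peptides between protein groups, ratio compression, correlated noise
across proteins, batch structure.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to every artifact of real MS data.

The transcriptome generator plants per-sample capture factors (applied to
spike-in and sample rows alike) and log-linear fold trajectories for a
chosen gene subset; with zero noise, spike-in rescaling recovers the
capture factors exactly and the ±2-fold classifier returns exactly the
planted genes (the fold cutoff uses a 1e-9 absolute tolerance so an
exactly-2-fold gene is not lost to rounding).

## Problem sizes and calibration checks

The recovery and error-control checks run at the emulated study scale —
3000 proteins, 4 ploidies × 3 replicates, 250 permutations — which keeps
the whole suite under a minute while leaving the statistics at realistic
granularity.  Exponent recovery is verified to ±0.02 over 10 seeds.  PDR
recovery is evaluated at the 0.1 FDR operating point, consistent with a
false-discovery tolerance of 0.1: with s0 = 0 and triplicates the t(4)
null tail genuinely overlaps the planted statistics, and at q < 0.05 the
attainable sensitivity is ≈ 0.85, while at q < 0.1 it is ≥ 0.94 with
observed false-discovery proportion 0 (the fold-change filter removes the
small-variance null hits).  The default `fdr_threshold` stays 0.05 for
analysis use.

## Known limitations

* The combined statistic is one reasonable sign-free combination; tools
  differ here, and magnitude comparisons across tools are not meaningful
  (the permutation null makes the *calibration* tool-independent).
* Permutation q values at 250 permutations are granular; exhaustive
  enumeration replaces sampling automatically only for small designs.
* The 2D enrichment p value is a per-dimension surrogate, isolated behind
  one function so a genuinely multivariate (Hotelling-type) test can be
  swapped in.
* The transcriptome branch implements plain proportional spike-in
  rescaling and a fold-change rule; array-specific corrections
  (probe-level normalisation, labeling-bias correction, moderated
  differential expression) are out of scope.
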