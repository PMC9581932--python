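"""Allometric scaling of proteome amount with ploidy.

The global trend is modelled as a power law ``amount = a * ploidy**b``.
With the haploid-anchored medians as input, the exponent *b* measures how
the proteome grows per genome copy: *b* = 1 is isometric (doubling the
genome doubles the protein amount), *b* < 1 is sublinear ("allometric")
scaling.  The fit is ordinary least squares of ``ln(median)`` on
``ln(ploidy)`` — the spreadsheet "power trendline" convention — either with
a free intercept (default, ``ln a`` estimated) or through the origin
(``a = 1`` fixed, natural when the 1N median is anchored at exactly 1).

Geometric null expectations for comparison: if cell volume scales by a
factor *v*, surface-like (2D) quantities are expected to scale by
``v**(2/3)`` and linear (1D) quantities by ``v**(1/3)``; volume doubling
hence predicts 1.59-fold area and 1.26-fold length changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tables_io import SCALE_LINEAR, RatioMatrix

METHOD_FREE_INTERCEPT = "loglog_ols_free_intercept"
METHOD_THROUGH_ORIGIN = "loglog_ols_through_origin"


@dataclass(frozen=True)
class PloidyMedianSeries:
    """Per-ploidy medians of relative protein amount."""

    ploidies: tuple[int, ...]
    medians: tuple[float, ...]
    n_values: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ploidies) != len(self.medians):
            raise ValueError("ploidies and medians differ in length")
        if list(self.ploidies) != sorted(set(self.ploidies)):
            raise ValueError("ploidies must be strictly increasing")
        if any(m <= 0 for m in self.medians):
            raise ValueError("medians must be positive")
        if self.n_values and len(self.n_values) != len(self.ploidies):
            raise ValueError("n_values length mismatch")

    def to_frame(self) -> pd.DataFrame:
        data = {"ploidy": self.ploidies, "median_relative_amount": self.medians}
        if self.n_values:
            data["n_values"] = self.n_values
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ScalingFit:
    """Result of a power-law fit ``amount = a * ploidy**b``.

    ``r_squared`` is the coefficient of determination on the log-log scale.
    ``stderr_b`` is the OLS standard error of the exponent (NaN when the fit
    is saturated).
    """

    exponent_b: float
    prefactor_a: float
    r_squared: float
    method: str
    n_points: int
    stderr_b: float = float("nan")

    def predict(self, ploidies) -> np.ndarray:
        """Fitted relative amounts at the given ploidies."""
        return self.prefactor_a * np.asarray(ploidies, dtype=float) ** self.exponent_b

    def summary(self) -> str:
        lines = [
            "Power-law scaling fit: amount = a * ploidy^b",
            f"  method        {self.method}",
            f"  n points      {self.n_points}",
            f"  exponent b    {self.exponent_b:.4f}  (SE {self.stderr_b:.4f})",
            f"  prefactor a   {self.prefactor_a:.4f}",
            f"  R^2 (log-log) {self.r_squared:.4f}",
        ]
        return "\n".join(lines)


def ploidy_medians(matrix: RatioMatrix) -> PloidyMedianSeries:
    """Median relative amount per ploidy over all finite values of all samples.

    Expects an anchored, linear-scale matrix so the medians read as amounts
    relative to the haploid state.
    """
    if matrix.scale != SCALE_LINEAR:
        raise ValueError("ploidy_medians expects a linear-scale matrix")
    ploidies, medians, counts = [], [], []
    for p in matrix.ploidies:
        pooled = matrix.values[matrix.samples_for_ploidy(p)].to_numpy(dtype=float).ravel()
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            raise ValueError(f"ploidy {p} has no finite values")
        ploidies.append(p)
        medians.append(float(np.median(pooled)))
        counts.append(int(pooled.size))
    return PloidyMedianSeries(tuple(ploidies), tuple(medians), tuple(counts))


def fit_power_law(
    series: PloidyMedianSeries, method: str = METHOD_FREE_INTERCEPT
) -> ScalingFit:
    """Fit ``amount = a * ploidy**b`` by OLS on the log-log scale."""
    return PloidyScalingModel(series).fit(method=method)


class PloidyScalingModel:
    """Power-law model of relative proteome amount versus ploidy.

    Construct from a :class:`PloidyMedianSeries` (or any positive
    ploidy/amount pairs) or, via :meth:`from_matrix`, directly from an
    anchored ratio matrix.  ``fit()`` returns a :class:`ScalingFit`.
    """

    def __init__(self, series: PloidyMedianSeries):
        self.series = series
        if len(series.ploidies) < 2:
            raise ValueError("need at least 2 points to fit a power law")

    @classmethod
    def from_matrix(cls, matrix: RatioMatrix) -> "PloidyScalingModel":
        return cls(ploidy_medians(matrix))

    @classmethod
    def from_points(cls, ploidies, amounts) -> "PloidyScalingModel":
        return cls(PloidyMedianSeries(tuple(int(p) for p in ploidies), tuple(float(a) for a in amounts)))

    def fit(self, method: str = METHOD_FREE_INTERCEPT) -> ScalingFit:
        x = np.log(np.asarray(self.series.ploidies, dtype=float))
        y = np.log(np.asarray(self.series.medians, dtype=float))
        n = x.size
        if method == METHOD_FREE_INTERCEPT:
            if n < 2:
                raise ValueError("free-intercept fit needs >= 2 points")
            res = sm.OLS(y, sm.add_constant(x)).fit()
            intercept, slope = res.params
            stderr = float(res.bse[1]) if n > 2 else float("nan")
            prefactor = float(np.exp(intercept))
        elif method == METHOD_THROUGH_ORIGIN:
            res = sm.OLS(y, x[:, None]).fit()
            slope = float(res.params[0])
            stderr = float(res.bse[0]) if n > 1 else float("nan")
            prefactor = 1.0
            intercept = 0.0
        else:
            raise ValueError(f"unknown fit method {method!r}")
        fitted = intercept + slope * x
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
        r2 = float(min(max(r2, 0.0), 1.0))
        return ScalingFit(
            exponent_b=float(slope),
            prefactor_a=prefactor,
            r_squared=r2,
            method=method,
            n_points=int(n),
            stderr_b=stderr,
        )


def per_protein_power_fits(matrix: RatioMatrix, min_points: int = 3) -> pd.DataFrame:
    """Fit the power law to each protein's own per-ploidy mean profile.

    Auxiliary view of the scaling: the distribution of per-protein
    exponents around the global *b*.  Proteins with fewer than
    ``min_points`` ploidies having any finite value get NaN rows.
    """
    if matrix.scale != SCALE_LINEAR:
        raise ValueError("per_protein_power_fits expects a linear-scale matrix")
    ploidies = matrix.ploidies
    group_cols = [matrix.samples_for_ploidy(p) for p in ploidies]
    arr = matrix.values.to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(matrix.values.columns)}

    rows = []
    for i, pid in enumerate(matrix.protein_ids):
        ps, amounts = [], []
        for p, cols in zip(ploidies, group_cols):
            vals = arr[i, [col_index[c] for c in cols]]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                ps.append(p)
                amounts.append(float(np.mean(vals)))
        if len(ps) >= max(min_points, 2):
            fit = PloidyScalingModel.from_points(ps, amounts).fit()
            rows.append((pid, fit.exponent_b, fit.prefactor_a, fit.r_squared, len(ps)))
        else:
            rows.append((pid, np.nan, np.nan, np.nan, len(ps)))
    return pd.DataFrame(
        rows, columns=["protein_id", "exponent_b", "prefactor_a", "r_squared", "n_points"]
    ).set_index("protein_id")


def geometric_expectation(volume_fold: float, dimensionality: int) -> float:
    """Expected fold change of a d-dimensional structure when volume scales.

    For a volume fold *v*, an isometric d-dimensional quantity scales as
    ``v**(d/3)``: doubling the volume gives 2^(2/3) = 1.59-fold area and
    2^(1/3) = 1.26-fold length.
    """
    if volume_fold <= 0:
        raise ValueError("volume_fold must be positive")
    if dimensionality not in (1, 2, 3):
        raise ValueError("dimensionality must be 1, 2 or 3")
    return float(volume_fold ** (dimensionality / 3.0))
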