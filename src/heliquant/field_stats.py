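"""Population-comparison and distribution statistics for field surveys.

Wild-caught cyanogen concentrations are right-skewed with a spike of
near-zero values, so group comparisons are run on square-root-transformed
values (one-way ANOVA with Tukey-Kramer follow-up), and distributions are
summarized with a zero-truncated, optionally weighted kernel density
estimate plus simple range/detection summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "FactorialAnovaResult",
    "DensityEstimate",
    "SkewSummary",
    "sqrt_anova",
    "tukey_hsd",
    "factorial_anova",
    "hedges_g",
    "pearson_correlation",
    "truncated_weighted_kde",
    "range_quartile_summary",
    "detection_summary",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    transform: str
    group_stats: pd.DataFrame           # raw-scale n/mean/SD per group
    _groups_transformed: dict = None    # retained for Tukey follow-up


def _group_arrays(values, groups):
    s = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups)})
    s = s.dropna()
    return {g: d["value"].to_numpy() for g, d in s.groupby("group")}


def sqrt_anova(values, groups) -> AnovaResult:
    """One-way ANOVA on square-root-transformed concentrations.

    Raw-scale group means and SDs are reported alongside the test, which
    is carried out on the transformed scale.
    """
    by = _group_arrays(values, groups)
    if len(by) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in by.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if np.any(v < 0):
            raise ValueError(f"negative values in group {g!r}; sqrt transform undefined")
    trans = {g: np.sqrt(v) for g, v in by.items()}
    k = len(by)
    n = sum(len(v) for v in by.values())
    allv = np.concatenate(list(trans.values()))
    if np.ptp(allv) == 0:  # constant data: no between-group signal
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*trans.values())
    gs = pd.DataFrame(
        {
            "group": list(by),
            "n": [len(v) for v in by.values()],
            "mean": [float(np.mean(v)) for v in by.values()],
            "sd": [float(np.std(v, ddof=1)) for v in by.values()],
        }
    )
    return AnovaResult(
        F=float(F), df_between=k - 1, df_within=n - k, p=float(p),
        transform="sqrt", group_stats=gs, _groups_transformed=trans,
    )


@dataclass
class TukeyResult:
    table: pd.DataFrame  # columns group1, group2, diff (transformed scale), p_adj

    def p_value(self, a, b) -> float:
        t = self.table
        row = t[((t.group1 == a) & (t.group2 == b)) | ((t.group1 == b) & (t.group2 == a))]
        if row.empty:
            raise KeyError((a, b))
        return float(row["p_adj"].iloc[0])


def tukey_hsd(anova: AnovaResult) -> TukeyResult:
    """Tukey-Kramer all-pairs comparisons on the same (transformed) scale
    as the ANOVA, valid for unequal group sizes."""
    if anova._groups_transformed is None:
        raise ValueError("AnovaResult lacks attached group data")
    names = list(anova._groups_transformed)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [anova._groups_transformed[g] for g in names]
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return TukeyResult(table=pd.DataFrame(rows))


@dataclass
class FactorialAnovaResult:
    table: pd.DataFrame  # index: factor_a, factor_b, interaction, Residual

    def F(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def factorial_anova(values, factor_a, factor_b) -> FactorialAnovaResult:
    """Two-way ANOVA with interaction (e.g. plant origin x watering
    treatment), type-II sums of squares."""
    df = pd.DataFrame(
        {"value": np.asarray(values, float),
         "fa": np.asarray(factor_a).astype(str),
         "fb": np.asarray(factor_b).astype(str)}
    ).dropna()
    if df["fa"].nunique() < 2 or df["fb"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")
    cells = df.groupby(["fa", "fb"]).size()
    full = df["fa"].nunique() * df["fb"].nunique()
    if len(cells) < full:
        raise ValueError("empty cells; interaction model is not estimable")
    model = ols("value ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={"C(fa)": "factor_a", "C(fb)": "factor_b", "C(fa):C(fb)": "interaction"}
    )
    return FactorialAnovaResult(table=table)


def hedges_g(group1, group2) -> float:
    """Hedges' g: the pooled-SD standardized mean difference with the
    exact small-sample bias correction J(df) = Gamma(df/2) /
    (sqrt(df/2) * Gamma((df-1)/2))."""
    a = np.asarray(group1, float)
    b = np.asarray(group2, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    d = (np.mean(a) - np.mean(b)) / np.sqrt(sp2)
    J = np.exp(gammaln(df / 2.0) - 0.5 * np.log(df / 2.0) - gammaln((df - 1) / 2.0))
    return float(d * J)


def pearson_correlation(x, y):
    """Pearson correlation with its t-test; returns (r, p, n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.var(x) <= 0 or np.var(y) <= 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    weights: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _reference_bandwidth(values: np.ndarray) -> float:
    """Normal-reference rule h = 0.9 * min(SD, IQR/1.34) * n^(-1/5)."""
    sd = np.std(values, ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-8)
    return 0.9 * spread * len(values) ** (-0.2)


def truncated_weighted_kde(
    values, weights=None, bandwidth: float | None = None, grid=None, n_grid: int = 512
) -> DensityEstimate:
    """Gaussian kernel density on [0, inf) for nonnegative concentrations.

    Each kernel is renormalized by its own mass on the nonnegative
    half-line (divide by Phi(x_i / h)), so the estimate integrates to one
    despite the boundary at zero; observation weights are normalized to
    sum to one.
    """
    x = np.asarray(values, float)
    if np.any(x < 0):
        raise ValueError("values must be nonnegative")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if weights is None:
        w = np.full(len(x), 1.0 / len(x))
    else:
        w = np.asarray(weights, float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative and not all zero")
        w = w / w.sum()
    h = float(bandwidth) if bandwidth is not None else _reference_bandwidth(x)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(0.0, x.max() + 6.0 * h, n_grid)
    grid = np.asarray(grid, float)
    mass = stats.norm.cdf(x / h)  # each kernel's mass on [0, inf)
    dens = np.zeros_like(grid)
    for xi, wi, mi in zip(x, w, mass):
        dens += wi * stats.norm.pdf(grid, loc=xi, scale=h) / mi
    return DensityEstimate(grid=grid, density=dens, bandwidth=h, weights=w)


@dataclass
class SkewSummary:
    range_min: float
    range_max: float
    frac_lower_quarter_of_range: float
    frac_upper_quarter_of_range: float
    threshold: float
    frac_below_threshold: float


def range_quartile_summary(values, threshold: float = 0.5) -> SkewSummary:
    """Fractions of observations in the lower and upper quarters of the
    observed *range* (not quantiles), plus the fraction below an absolute
    concentration threshold.  A strongly right-skewed sample piles up in
    the lower quarter of its range."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("constant data: range is zero")
    span = hi - lo
    lower = float(np.mean(x <= lo + 0.25 * span))
    upper = float(np.mean(x >= lo + 0.75 * span))
    below = float(np.mean(x < threshold))
    return SkewSummary(
        range_min=lo, range_max=hi,
        frac_lower_quarter_of_range=lower,
        frac_upper_quarter_of_range=upper,
        threshold=threshold, frac_below_threshold=below,
    )


def detection_summary(values, limit: float = 0.0):
    """Fraction of samples with a signal above the detection limit and the
    mean concentration over that detected subset (NaN if none).
    Returns (detected_fraction, mean_of_detected)."""
    x = np.asarray(values, float)
    if len(x) < 1:
        raise ValueError("need at least 1 observation")
    if limit < 0:
        raise ValueError("detection limit must be nonnegative")
    detected = x > limit
    frac = float(np.mean(detected))
    mean_det = float(np.mean(x[detected])) if detected.any() else float("nan")
    return frac, mean_det
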