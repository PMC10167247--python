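"""The correlation/ANOVA layer tying the per-taxon ratios together.

Operations:

* :func:`splicing_ratio` — alternative-splicing isoforms over total
  transcripts per group;
* :func:`pearson_r2` — Pearson correlation with the t-transform p-value
  and the least-squares line;
* :func:`anova_dunnett` — one-way ANOVA plus Dunnett-style many-to-one
  comparisons, adjusted by seeded Monte Carlo of the max-|t| null under
  pooled variance;
* :func:`bootstrap_partial_correlation` — partial correlations by
  residualization, with case-resampling bootstrap CIs and p-values;
* :func:`correlation_report` — the standard trio of scatter relationships
  (duplication ratio ~ divergence time, duplication ~ chromosome ratio,
  mean omega ~ chromosome ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class UndefinedRatioError(ZeroDivisionError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# splicing ratio
# ---------------------------------------------------------------------------

def splicing_ratio(
    isoform_table: pd.DataFrame,
    by: str | list[str] = "species",
    numerator: str = "extra",
) -> pd.Series:
    """Alternative-splicing isoforms over total transcripts per group.

    ``isoform_table`` needs columns (species, gene, isoform_id) plus any
    grouping columns.  ``numerator='extra'`` counts, per gene with >= 2
    isoforms, the isoforms beyond the first; ``'all'`` counts every
    isoform of such genes.  The denominator is the total transcript count
    of the group.
    """
    if numerator not in ("extra", "all"):
        raise ValueError(f"numerator must be 'extra' or 'all', got {numerator!r}")
    for col in ("gene", "isoform_id"):
        if col not in isoform_table.columns:
            raise ValueError(f"isoform table missing column {col!r}")
    if isoform_table.empty:
        raise UndefinedRatioError("empty isoform table")

    def _one(group: pd.DataFrame) -> float:
        total = len(group)
        if total == 0:
            raise UndefinedRatioError("empty group")
        k = group.groupby("gene", observed=True)["isoform_id"].nunique()
        if numerator == "extra":
            num = int((k[k >= 2] - 1).sum())
        else:
            num = int(k[k >= 2].sum())
        return num / total

    grouped = isoform_table.groupby(by, observed=True)
    return grouped.apply(_one, include_groups=False).rename("splicing_ratio")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    r2: float
    p_value: float
    n: int
    slope: float
    intercept: float


def pearson_r2(x, y) -> CorrelationResult:
    """Pearson r, R^2, the t-transform p-value (n-2 df), and the OLS line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue), r2=float(fit.rvalue**2), p_value=float(fit.pvalue),
        n=int(x.size), slope=float(fit.slope), intercept=float(fit.intercept),
    )


# ---------------------------------------------------------------------------
# ANOVA + Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    p_value: float
    group_means: dict[str, float]
    dunnett_adjusted: dict[str, float]
    control: str
    n_mc: int


def anova_dunnett(
    groups: dict[str, np.ndarray],
    control: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> AnovaResult:
    """One-way ANOVA with Dunnett-adjusted comparisons against a control.

    Each non-control group's t statistic (pooled variance, N - k df) is
    compared with a seeded Monte Carlo sample of the null distribution of
    max |t| over all comparisons; adjusted p = (1 + #{max >= |t|}) /
    (n_mc + 1).  Controlling max |t| gives family-wise error control at
    the nominal level.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = [control] + sorted(g for g in groups if g != control)
    data = {g: np.asarray(groups[g], dtype=float) for g in names}
    sizes = {g: data[g].size for g in names}
    if any(n < 2 for n in sizes.values()):
        raise ValueError("every group needs n >= 2")

    F, p = sps.f_oneway(*(data[g] for g in names))
    N = sum(sizes.values())
    k = len(names)
    df = N - k
    ss_within = sum(((data[g] - data[g].mean()) ** 2).sum() for g in names)
    s2 = ss_within / df
    nc = sizes[control]
    mc_mean = data[control].mean()
    t_obs = {
        g: (data[g].mean() - mc_mean) / math.sqrt(s2 * (1.0 / sizes[g] + 1.0 / nc))
        for g in names[1:]
    }

    max_null = _max_abs_t_null(
        [sizes[g] for g in names], n_mc, np.random.default_rng(seed)
    )
    adjusted = {
        g: float((1 + np.count_nonzero(max_null >= abs(t))) / (n_mc + 1))
        for g, t in t_obs.items()
    }
    return AnovaResult(
        F=float(F), p_value=float(p),
        group_means={g: float(data[g].mean()) for g in names},
        dunnett_adjusted=adjusted, control=control, n_mc=n_mc,
    )


def _max_abs_t_null(sizes: list[int], n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Null max-|t| over many-to-one comparisons; sizes[0] is the control."""
    k = len(sizes)
    N = sum(sizes)
    df = N - k
    means = np.empty((n_mc, k))
    ss = np.zeros(n_mc)
    # draw per group in blocks to bound memory at n_mc x max(n)
    for gi, n in enumerate(sizes):
        x = rng.standard_normal((n_mc, n))
        m = x.mean(axis=1)
        means[:, gi] = m
        ss += ((x - m[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    nc = sizes[0]
    tmax = np.zeros(n_mc)
    for gi in range(1, k):
        t = (means[:, gi] - means[:, 0]) / np.sqrt(s2 * (1.0 / sizes[gi] + 1.0 / nc))
        np.maximum(tmax, np.abs(t), out=tmax)
    return tmax


# ---------------------------------------------------------------------------
# bootstrap partial correlation
# ---------------------------------------------------------------------------

def _partial_r(y: np.ndarray, X: np.ndarray, j: int) -> float:
    """Correlation of y and X[:, j] after removing the other predictors."""
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    rx = X[:, j] - design @ np.linalg.lstsq(design, X[:, j], rcond=None)[0]
    denom = math.sqrt((ry @ ry) * (rx @ rx))
    if denom == 0:
        return math.nan
    return float((ry @ rx) / denom)


def bootstrap_partial_correlation(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict[str, dict[str, float]]:
    """Partial correlation of each predictor with the response, bootstrapped.

    Partial r is computed by residualizing both the response and the
    predictor against the remaining predictors (with intercept); with a
    single predictor it reduces to the plain Pearson r.  Rows are
    case-resampled ``n_boot`` times for percentile CIs and a two-sided
    sign-based p-value: p = 2 min(P(r* >= 0), P(r* <= 0)).
    """
    if n_boot < 199:
        raise ValueError("n_boot must be >= 199")
    cols = [response] + list(predictors)
    cc = table[cols].dropna()
    n = len(cc)
    if n < len(predictors) + 3:
        raise ValueError(
            f"only {n} complete cases for {len(predictors)} predictors; need >= "
            f"{len(predictors) + 3}"
        )
    y = cc[response].to_numpy(dtype=float)
    X = cc[list(predictors)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    alpha = 1.0 - ci
    out: dict[str, dict[str, float]] = {}
    boots = np.empty((n_boot, len(predictors)))
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        yb, Xb = y[idx], X[idx]
        for j in range(len(predictors)):
            boots[b, j] = _partial_r(yb, Xb, j)
    for j, name in enumerate(predictors):
        col = boots[:, j]
        col = col[~np.isnan(col)]
        p = 2.0 * min(np.mean(col >= 0.0), np.mean(col <= 0.0))
        out[name] = {
            "partial_r": _partial_r(y, X, j),
            "ci_low": float(np.percentile(col, 100 * alpha / 2)),
            "ci_high": float(np.percentile(col, 100 * (1 - alpha / 2))),
            "p_value": float(min(p, 1.0)),
            "n": n,
            "n_boot": int(n_boot),
        }
    return out


# ---------------------------------------------------------------------------
# the standard correlation trio
# ---------------------------------------------------------------------------

RATIO_COLUMNS = [
    "taxon", "family", "duplication_ratio", "chromosome_ratio",
    "splicing_ratio", "divergence_time", "mean_w",
]

_PAIRS = {
    "duplication_vs_divergence_time": ("divergence_time", "duplication_ratio"),
    "duplication_vs_chromosome": ("chromosome_ratio", "duplication_ratio"),
    "omega_vs_chromosome": ("chromosome_ratio", "mean_w"),
}


def correlation_report(table: pd.DataFrame) -> dict[str, CorrelationResult | None]:
    """The three scatter relationships of the ratio table.

    Duplication ratio against divergence time and against chromosome
    ratio, and mean omega against chromosome ratio; each computed on the
    complete cases of its own column pair.  A pair that is undefined
    (constant column, or fewer than 3 complete cases) maps to None rather
    than failing the whole report.
    """
    out: dict[str, CorrelationResult | None] = {}
    for name, (xcol, ycol) in _PAIRS.items():
        sub = table[[xcol, ycol]].dropna()
        try:
            out[name] = pearson_r2(sub[xcol].to_numpy(), sub[ycol].to_numpy())
        except (UndefinedCorrelationError, ValueError):
            out[name] = None
    return out
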