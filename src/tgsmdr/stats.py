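"""Case-control association statistics: Pearson chi-square with Cohen's w,
a priori chi-square power, odds ratios, Mann-Whitney ROC/AUC and t-tests."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    w: float  #: Cohen's effect size sqrt(chi2 / n)
    n: int


def chi2_contingency(table: Sequence[Sequence[float]] | np.ndarray) -> Chi2Result:
    """Pearson chi-square test of independence on an r x c count table.

    No Yates continuity correction is applied.  Cohen's effect size
    w = sqrt(chi2 / n) is attached.  A zero row or column marginal is an
    error naming the empty margin.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"row {i} of the contingency table is empty")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"column {j} of the contingency table is empty")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    n = int(obs.sum())
    return Chi2Result(chi2=float(chi2), df=int(df), p=float(p), w=math.sqrt(chi2 / n), n=n)


def chi2_power(n: float, w: float, df: int = 1, alpha: float = 0.05) -> float:
    """Power of a Pearson chi-square test at sample size n and effect size w.

    The test statistic is noncentral chi-square with noncentrality n * w^2
    under the alternative; power is the probability it exceeds the central
    critical value at ``alpha``.
    """
    crit = stats.chi2.ppf(1 - alpha, df)
    return float(stats.ncx2.sf(crit, df, n * w * w))


def chi2_power_n(
    w: float, df: int = 1, alpha: float = 0.05, power: float = 0.8
) -> dict[str, float]:
    """Smallest sample size giving a chi-square test the target power.

    Solves P[chi2_noncentral(df, n w^2) > chi2_crit(alpha, df)] = power for n
    by root-finding (power is monotone increasing in n).  Returns
    ``{"n_exact": real-valued solution, "n_min": smallest integer with
    power >= target}``.
    """
    if w <= 0:
        raise ValueError("effect size w must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    lo, hi = 1.0, 16.0
    while chi2_power(hi, w, df, alpha) < power:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("power target unreachable")  # pragma: no cover
    n_exact = optimize.brentq(
        lambda n: chi2_power(n, w, df, alpha) - power, lo, hi, xtol=1e-9, rtol=1e-12
    )
    n_min = math.ceil(n_exact - 1e-9)
    while chi2_power(n_min, w, df, alpha) < power:  # guard against ceil rounding
        n_min += 1
    return {"n_exact": float(n_exact), "n_min": int(n_min)}


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    confidence: float


def odds_ratio(
    a: float, b: float, c: float, d: float, confidence: float = 0.95
) -> OddsRatioResult:
    """Odds ratio ad/bc for a 2x2 table [[a, b], [c, d]] with Woolf's
    log-method confidence interval.

    The Haldane-Anscombe correction (+0.5 to every cell) is applied if and
    only if some cell is zero.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(0.5 + confidence / 2)
    return OddsRatioResult(
        odds_ratio=or_,
        ci_lower=math.exp(math.log(or_) - z * se),
        ci_upper=math.exp(math.log(or_) + z * se),
        confidence=confidence,
    )


def odds_ratio_from_props(p1: float, p2: float) -> float:
    """Odds ratio comparing two proportions: (p1/(1-p1)) / (p2/(1-p2))."""
    for p in (p1, p2):
        if not (0 < p < 1):
            raise ValueError("proportions must lie strictly in (0, 1)")
    return (p1 / (1 - p1)) / (p2 / (1 - p2))


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    p: float  #: two-sided p-value against AUC = 0.5
    n_pos: int
    n_neg: int


def roc_auc(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    *,
    confidence: float = 0.95,
    method: str = "hanley",
) -> RocResult:
    """AUC by the Mann-Whitney pair-counting statistic (ties count one half).

    The confidence interval uses the Hanley-McNeil standard error by default
    (``method="delong"`` for the DeLong covariance-based SE); the p-value is
    the normal approximation of (AUC - 0.5) / SE.  For a degenerate SE of 0
    with AUC != 0.5, p is reported as 0.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    n1, n0 = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    if method == "hanley":
        q1 = auc / (2 - auc)
        q2 = 2 * auc * auc / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
            n1 * n0
        )
        se = math.sqrt(max(var, 0.0))
    elif method == "delong":
        # Structural components: V10_i = P(score_neg < pos_i) + 0.5 P(tie).
        v10 = np.array(
            [(np.sum(neg < x) + 0.5 * np.sum(neg == x)) / n0 for x in pos]
        )
        v01 = np.array(
            [(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / n1 for y in neg]
        )
        var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0 if n1 > 1 and n0 > 1 else 0.0
        se = math.sqrt(max(var, 0.0))
    else:
        raise ValueError(f"unknown AUC CI method {method!r}")

    z = stats.norm.ppf(0.5 + confidence / 2)
    lower = max(0.0, auc - z * se)
    upper = min(1.0, auc + z * se)
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return RocResult(
        auc=float(auc), ci_lower=lower, ci_upper=upper, p=p, n_pos=n1, n_neg=n0
    )


def t_test_ind(
    x: Sequence[float], y: Sequence[float], *, equal_var: bool = True
) -> dict[str, float]:
    """Two-sided independent-samples t-test (pooled-variance Student's by
    default; ``equal_var=False`` for Welch's)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else (
        len(x) + len(y) - 2 if equal_var else float("nan")
    )
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue)}
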