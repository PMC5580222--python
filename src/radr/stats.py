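"""Statistical primitives used by every pipeline stage.

Rank tests follow an explicit small-sample policy: the paired signed-rank
test uses the exact conditional distribution (computed by dynamic
programming over the observed absolute-rank multiset, so ties are handled
exactly) for n <= 25 informative pairs and a tie-corrected normal
approximation with continuity correction above.  Cox models are maximum
partial likelihood fits with Efron tie handling (delegated to lifelines);
the Kaplan-Meier estimator is computed directly by the product-limit
formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import SurvivalRecord, survival_frame
from .errors import ValidationError

EXACT_WILCOXON_MAX_N = 25


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class CoxFit:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    converged: bool

    def hazard_ratio(self, covariate: str) -> float:
        return float(np.exp(self.coefficients[covariate]))


def _clean_pairs(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    return a[mask], b[mask]


def _signed_rank_exact_p(ranks: np.ndarray, t_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum via DP over sign flips.

    Works with midranks (multiples of 1/2) by doubling to integers.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    t2 = int(round(2 * t_plus))
    p_le = counts[: t2 + 1].sum()
    p_ge = counts[t2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_wilcoxon(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped ("wilcox" zero policy); if all differences
    are zero a degenerate result (statistic 0, p 1) is returned.
    """
    a, b = _clean_pairs(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, "paired_wilcoxon", degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= EXACT_WILCOXON_MAX_N:
        p = _signed_rank_exact_p(ranks, t_plus)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return TestResult(t_plus, 1.0, "paired_wilcoxon", degenerate=True)
        z = (t_plus - mu - 0.5 * np.sign(t_plus - mu)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(t_plus, p, "paired_wilcoxon")


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return TestResult(a.size * b.size / 2.0, 1.0, "mann_whitney", degenerate=True)
    small = (a.size + b.size) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test with chi-square p (k-1 df)."""
    cleaned = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
        cleaned.append(g)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(cleaned)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "kruskal_wallis", degenerate=True)
    res = sps.kruskal(*cleaned)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal_wallis")


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((labels.size, 0))


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def anova_group_effect(
    values: Sequence[float],
    group: Sequence,
    block: Sequence,
    *,
    interaction: bool = False,
) -> TestResult:
    """F test for the group main effect adjusting for a blocking factor.

    Fits the additive linear model ``value ~ group + block`` (type II sum of
    squares; with ``interaction=True`` the full model additionally includes
    the group x block interaction, and the group F tests all group-involving
    terms jointly against the block-only model).
    """
    y = np.asarray(values, dtype=float)
    group = np.asarray(group)
    block = np.asarray(block)
    if not (y.size == group.size == block.size):
        raise ValueError("values, group and block must be aligned")
    mask = np.isfinite(y)
    y, group, block = y[mask], group[mask], block[mask]
    if pd.unique(group).size < 2:
        return TestResult(0.0, 1.0, "anova_group", degenerate=True)
    if pd.unique(block).size < 2 and not interaction:
        # blocking factor constant: reduces to one-way ANOVA
        pass
    n = y.size
    ones = np.ones((n, 1))
    G = _dummies(group)
    B = _dummies(block)
    X_red = np.hstack([ones, B])
    X_full = np.hstack([ones, G, B])
    if interaction:
        inter = np.column_stack([G[:, i] * B[:, j]
                                 for i in range(G.shape[1]) for j in range(B.shape[1])]) \
            if G.shape[1] and B.shape[1] else np.empty((n, 0))
        X_full = np.hstack([X_full, inter])
    rss_full, rank_full = _rss(X_full, y)
    rss_red, rank_red = _rss(X_red, y)
    df_num = rank_full - rank_red
    df_den = n - rank_full
    if df_num <= 0 or df_den <= 0:
        return TestResult(0.0, 1.0, "anova_group", degenerate=True)
    ss_group = max(rss_red - rss_full, 0.0)
    scale = max(float(y @ y), 1.0)
    if ss_group <= 1e-12 * scale:
        return TestResult(0.0, 1.0, "anova_group", degenerate=(rss_full <= 1e-12 * scale))
    if rss_full <= 1e-12 * scale:
        return TestResult(float("inf"), 0.0, "anova_group")
    f_stat = (ss_group / df_num) / (rss_full / df_den)
    p = float(sps.f.sf(f_stat, df_num, df_den))
    return TestResult(float(f_stat), p, "anova_group")


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with two-sided t-based p (n-2 df)."""
    x, y = _clean_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(0.0, 1.0, "pearson", degenerate=True)
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "pearson")


def adjust_pvalues(p: Sequence[float], method: str = "holm") -> list[float]:
    """Holm step-down (default) or Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    if method == "holm":
        running = 0.0
        for i, idx in enumerate(order):
            running = max(running, (m - i) * p[idx])
            adj[idx] = min(1.0, running)
    elif method == "bh":
        running = 1.0
        for i, idx in enumerate(order[::-1]):
            rank = m - i
            running = min(running, m / rank * p[idx])
            adj[idx] = min(1.0, running)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return adj.tolist()


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: Mapping[str, Sequence[float]],
) -> CoxFit:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    ``covariates`` maps covariate name to a vector aligned with ``records``.
    Raises on zero events or collinear covariates; a non-convergent fit is
    returned with ``converged=False`` after a lightly penalized refit.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    if not records:
        raise ValueError("no survival records")
    surv = survival_frame(records)[["time", "event"]].reset_index(drop=True)
    if surv["event"].sum() < 1:
        raise ValueError("no events in survival records")
    df = surv.copy()
    names = list(covariates)
    if not names:
        raise ValueError("at least one covariate required")
    for name in names:
        vec = np.asarray(covariates[name], dtype=float)
        if vec.size != len(records):
            raise ValueError(f"covariate {name!r} not aligned with records")
        df[name] = vec
    X = df[names].to_numpy()
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.where(sd == 0)[0]]
        raise ValidationError(f"degenerate (constant) covariates: {bad}")
    if np.linalg.cond((X - X.mean(axis=0)) / sd) > 1e8:
        raise ValidationError("covariates are collinear")

    def _fit(penalizer: float):
        cph = CoxPHFitter(penalizer=penalizer)
        cph.fit(df, duration_col="time", event_col="event")
        return cph

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph = _fit(0.0)
        except ConvergenceError:
            cph = _fit(0.1)
            converged = False
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    summary = cph.summary
    return CoxFit(
        coefficients={n: float(summary.loc[n, "coef"]) for n in names},
        standard_errors={n: float(summary.loc[n, "se(coef)"]) for n in names},
        p_values={n: float(summary.loc[n, "p"]) for n in names},
        converged=converged,
    )


class KaplanMeierCurve:
    """Right-continuous non-increasing product-limit survival curve."""

    def __init__(self, times: np.ndarray, survival: np.ndarray, n: int, n_events: int):
        self.times = times
        self.survival = survival
        self.n = n
        self.n_events = n_events

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])[idx]
        return float(vals) if vals.ndim == 0 else vals


def kaplan_meier(records: Sequence[SurvivalRecord]) -> KaplanMeierCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set silently."""
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
    return KaplanMeierCurve(uniq, np.array(surv), n=len(records),
                            n_events=int(events.sum()))


def logrank_test(
    records: Sequence[SurvivalRecord], group: Sequence,
) -> TestResult:
    """Two-group log-rank chi-square test (1 df)."""
    from lifelines.statistics import logrank_test as _ll_logrank

    group = np.asarray(group)
    if group.size != len(records):
        raise ValueError("group labels must align with records")
    levels = pd.unique(group)
    if levels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 non-empty groups, got {levels.size}")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    if events.sum() < 1:
        raise ValueError("no events in survival records")
    m0, m1 = group == levels[0], group == levels[1]
    res = _ll_logrank(times[m0], times[m1], events[m0], events[m1])
    return TestResult(float(res.test_statistic), float(res.p_value), "logrank")
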