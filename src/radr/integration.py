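"""Downstream association analyses of a per-sample score.

Median-split survival stratification, score comparisons across labelled
groups (subtype, HPV status, genotype flags), and Pearson correlation
screens against feature matrices (hallmark enrichment scores, protein
panels, drug IC50 panels) with a printed-threshold hit rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ScoreTable, SurvivalRecord
from .stats import (
    KaplanMeierCurve,
    TestResult,
    adjust_pvalues,
    kaplan_meier,
    kruskal_wallis,
    logrank_test,
    mann_whitney,
    pearson,
)

SIGNS = ("any", "positive", "negative")


@dataclass
class StratifiedSurvivalResult:
    split_value: float
    group_sizes: tuple[int, int]  # (low, high)
    km_low: KaplanMeierCurve
    km_high: KaplanMeierCurve
    logrank: TestResult


@dataclass
class GroupComparisonResult:
    test: TestResult
    medians: dict[str, float]
    group_sizes: dict[str, int]
    dropped: list[str]


@dataclass
class CorrelationScreenResult:
    table: pd.DataFrame  # feature, r, p_value, adjusted_p, n, hit
    r_min: float
    p_max: float
    sign: str

    @property
    def hits(self) -> list[str]:
        return self.table.loc[self.table["hit"], "feature"].tolist()


def median_split_survival(
    scores: ScoreTable, survival: Sequence[SurvivalRecord],
) -> StratifiedSurvivalResult:
    """Kaplan-Meier + log-rank between groups split at the median score.

    Subjects at or below the median form the low group (ties go low).
    """
    by_id = {r.sample_id: r for r in survival}
    shared = [s for s in scores.sample_ids if s in by_id]
    if len(shared) < 10:
        raise ValueError(f"need >= 10 subjects with score and survival, got {len(shared)}")
    vals = scores.scores[shared]
    if vals.nunique() == 1:
        raise ValueError("all scores equal: no median split possible")
    median = float(np.median(vals))
    high_ids = [s for s in shared if vals[s] > median]
    low_ids = [s for s in shared if vals[s] <= median]
    if not high_ids:
        raise ValueError("median split produced an empty high group (score ties)")
    records = [by_id[s] for s in low_ids + high_ids]
    labels = ["low"] * len(low_ids) + ["high"] * len(high_ids)
    return StratifiedSurvivalResult(
        split_value=median,
        group_sizes=(len(low_ids), len(high_ids)),
        km_low=kaplan_meier([by_id[s] for s in low_ids]),
        km_high=kaplan_meier([by_id[s] for s in high_ids]),
        logrank=logrank_test(records, labels),
    )


def compare_groups(
    scores: ScoreTable, labels: Mapping[str, str],
) -> GroupComparisonResult:
    """Score comparison across labelled groups.

    Two groups: Mann-Whitney; more: Kruskal-Wallis.  Singleton groups are
    dropped with a warning.
    """
    groups: dict[str, list[float]] = {}
    for sid in scores.sample_ids:
        lab = labels.get(sid)
        if lab is not None:
            groups.setdefault(str(lab), []).append(scores[sid])
    dropped = [lab for lab, vals in groups.items() if len(vals) < 2]
    if dropped:
        warnings.warn(f"singleton groups excluded: {sorted(dropped)}", stacklevel=2)
    groups = {lab: vals for lab, vals in groups.items() if len(vals) >= 2}
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups with >= 2 members, got {len(groups)}")
    names = sorted(groups)
    if len(names) == 2:
        test = mann_whitney(groups[names[0]], groups[names[1]])
    else:
        test = kruskal_wallis([groups[n] for n in names])
    return GroupComparisonResult(
        test=test,
        medians={n: float(np.median(groups[n])) for n in names},
        group_sizes={n: len(groups[n]) for n in names},
        dropped=sorted(dropped),
    )


def correlate_with_matrix(
    scores: ScoreTable,
    features: pd.DataFrame,
    r_min: float = 0.2,
    p_max: float = 0.01,
    sign: str = "any",
    *,
    min_n: int = 10,
) -> CorrelationScreenResult:
    """Pearson screen of a score against each row of a feature matrix.

    Correlations are pairwise-complete with a minimum of ``min_n`` shared
    observations per feature.  The hit rule uses the raw thresholds exactly
    (|r| >= r_min, signed per ``sign``; p <= p_max); Holm-adjusted p-values
    are reported alongside.
    """
    if sign not in SIGNS:
        raise ValueError(f"sign must be one of {SIGNS}")
    shared = [s for s in scores.sample_ids if s in features.columns]
    if not shared:
        raise ValueError("no shared samples between scores and feature matrix")
    svec = scores.scores[shared].to_numpy()
    rows = []
    for feature in features.index:
        fvec = features.loc[feature, shared].to_numpy(float)
        mask = np.isfinite(fvec) & np.isfinite(svec)
        n = int(mask.sum())
        if n < max(3, min_n):
            rows.append((feature, np.nan, np.nan, n, False))
            continue
        res = pearson(svec[mask], fvec[mask])
        if res.degenerate:
            rows.append((feature, np.nan, np.nan, n, False))
            continue
        r, p = res.statistic, res.p_value
        ok_sign = (sign == "any" and abs(r) >= r_min) or \
                  (sign == "positive" and r >= r_min) or \
                  (sign == "negative" and r <= -r_min)
        rows.append((feature, r, p, n, bool(ok_sign and p <= p_max)))
    df = pd.DataFrame(rows, columns=["feature", "r", "p_value", "n", "hit"])
    valid = df["p_value"].notna()
    adj = pd.Series(np.nan, index=df.index)
    if valid.any():
        adj[valid] = adjust_pvalues(df.loc[valid, "p_value"].tolist(), method="holm")
    df["adjusted_p"] = adj
    df = df[["feature", "r", "p_value", "adjusted_p", "n", "hit"]]
    df = df.sort_values("r", ascending=False, na_position="last").reset_index(drop=True)
    return CorrelationScreenResult(df, r_min=r_min, p_max=p_max, sign=sign)


def multi_dataset_consensus(
    screens: Sequence[CorrelationScreenResult],
) -> pd.DataFrame:
    """Features that are hits with a consistent sign in every screen.

    Returns a frame (feature, mean_r, n_screens) sorted by |mean_r|.
    """
    if not screens:
        raise ValueError("need at least one screen")
    namespaces = [set(s.table["feature"]) for s in screens]
    common = set.intersection(*namespaces)
    if not common:
        raise ValueError("screens share no features")
    rows = []
    for feature in sorted(common):
        rs = []
        hit_all = True
        for s in screens:
            row = s.table.loc[s.table["feature"] == feature].iloc[0]
            if not row["hit"]:
                hit_all = False
                break
            rs.append(row["r"])
        if not hit_all:
            continue
        signs = {np.sign(r) for r in rs}
        if len(signs) > 1:
            continue
        rows.append((feature, float(np.mean(rs)), len(screens)))
    df = pd.DataFrame(rows, columns=["feature", "mean_r", "n_screens"])
    return df.reindex(df["mean_r"].abs().sort_values(ascending=False).index) \
             .reset_index(drop=True)
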