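"""Three-stage gene-selection funnel producing a directional signature.

Stage 1: paired tumor-vs-normal differential expression (paired signed-rank
test on log2 values, signed fold change from linear-scale means, Holm
adjustment, FDR < 0.05 and |FC| > 1).
Stage 2: radioresistant-vs-radiosensitive cell-line comparison pooled across
post-irradiation timepoints (two-factor additive ANOVA adjusting for the
timepoint, same thresholds).
Stage 3: per-gene multivariate Cox screen on irradiated patients (gene
expression as a continuous per-log2-unit covariate plus age, nodal stage and
tumor stage; raw p < 0.05, no multiplicity adjustment at this stage).

The signature is the intersection of the three stage outputs, by default
restricted to genes whose stage-1 and stage-2 directions agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    ExpressionMatrix,
    SampleAnnotation,
    SignatureGeneSet,
    SurvivalRecord,
    validate_pairs,
)
from .errors import ValidationError
from .stats import adjust_pvalues, anova_group_effect, cox_fit, mann_whitney, paired_wilcoxon

MAX_MISSING_FRACTION = 0.2


@dataclass
class FunnelThresholds:
    fdr_max: float = 0.05
    abs_fc_min: float = 1.0
    cox_p_max: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1) or not (0 < self.cox_p_max <= 1):
            raise ValidationError("fdr_max and cox_p_max must lie in (0, 1]")
        if self.abs_fc_min < 1:
            raise ValidationError("abs_fc_min must be >= 1")


@dataclass
class DEGeneResult:
    gene: str
    fc: float
    p_value: float
    fdr: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("UP", "DN"):
            raise ValidationError(f"direction must be UP or DN, got {self.direction!r}")
        if abs(self.fc) < 1:
            raise ValidationError(f"|fc| must be >= 1 (signed-ratio convention), got {self.fc}")
        if (self.fc > 0) != (self.direction == "UP") and self.fc != 1.0:
            raise ValidationError(f"gene {self.gene}: fc sign inconsistent with direction")


@dataclass
class CoxGeneResult:
    gene: str
    hr: float
    p_value: float

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValidationError(f"gene {self.gene}: hazard ratio must be positive")


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Signed ratio of two linear-scale means: a/b if >= 1 else -b/a."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("means must be positive (apply pseudocount upstream)")
    ratio = mean_a / mean_b
    return ratio if ratio >= 1 else -1.0 / ratio


def classify_cell_line(sf2: Optional[float] = None, auc: Optional[float] = None,
                       mode: str = "sf2") -> str:
    """Radiosensitivity label from the clonogenic assay.

    sf2 mode: radiosensitive below 0.2, radioresistant above 0.8,
    intermediate otherwise.  auc mode: radioresistant above 2.0.
    """
    if mode == "sf2":
        if sf2 is None:
            raise ValueError("sf2 required in sf2 mode")
        if sf2 < 0.2:
            return "radiosensitive"
        if sf2 > 0.8:
            return "radioresistant"
        return "intermediate"
    if mode == "auc":
        if auc is None:
            raise ValueError("auc required in auc mode")
        return "radioresistant" if auc > 2.0 else "radiosensitive"
    raise ValueError(f"unknown mode {mode!r}")


def _testable_genes(expr: ExpressionMatrix) -> list[str]:
    frac = expr.missing_fraction()
    return [g for g in expr.gene_ids if frac[g] <= MAX_MISSING_FRACTION]


def _de_results(genes, fcs, pvals, thresholds) -> list[DEGeneResult]:
    fdrs = adjust_pvalues(pvals, method="holm")
    out = []
    for gene, fc, p, fdr in zip(genes, fcs, pvals, fdrs):
        if fdr < thresholds.fdr_max and abs(fc) > thresholds.abs_fc_min:
            out.append(DEGeneResult(gene, float(fc), float(p), float(fdr),
                                    "UP" if fc > 0 else "DN"))
    return sorted(out, key=lambda r: r.gene)


def stage1_tumor_vs_normal(
    expr: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    thresholds: FunnelThresholds | None = None,
) -> list[DEGeneResult]:
    """Paired tumor-vs-normal differential expression."""
    thresholds = thresholds or FunnelThresholds()
    pairs = validate_pairs(annotations)
    in_matrix = set(expr.sample_ids)
    pairs = {pid: tn for pid, tn in pairs.items()
             if tn[0] in in_matrix and tn[1] in in_matrix}
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 complete tumor/normal pairs, found {len(pairs)}")
    tumor_ids = [tn[0] for tn in pairs.values()]
    normal_ids = [tn[1] for tn in pairs.values()]
    genes = _testable_genes(expr)
    tumor = expr.values.loc[genes, tumor_ids].to_numpy()
    normal = expr.values.loc[genes, normal_ids].to_numpy()
    fcs, pvals = [], []
    for i in range(len(genes)):
        res = paired_wilcoxon(tumor[i], normal[i])
        mask = np.isfinite(tumor[i]) & np.isfinite(normal[i])
        fc = signed_fold_change(
            float(np.mean(2.0 ** tumor[i][mask])),
            float(np.mean(2.0 ** normal[i][mask])),
        )
        fcs.append(fc)
        pvals.append(res.p_value)
    return _de_results(genes, fcs, pvals, thresholds)


def _stage2_f_vectorized(Y: np.ndarray, group: np.ndarray, block: np.ndarray):
    """Group-effect F and p for many genes at once (additive model).

    Algebraically identical to per-gene :func:`anova_group_effect`; the two
    routes are cross-checked in the test suite.
    """
    n = Y.shape[1]
    ones = np.ones((n, 1))
    g_levels = pd.unique(group)
    b_levels = pd.unique(block)
    G = np.column_stack([(group == lv).astype(float) for lv in g_levels[1:]])
    B = np.column_stack([(block == lv).astype(float) for lv in b_levels[1:]]) \
        if len(b_levels) > 1 else np.empty((n, 0))
    X_full = np.hstack([ones, G, B])
    X_red = np.hstack([ones, B])

    def rss(X):
        Q, _ = np.linalg.qr(X)
        resid = Y.T - Q @ (Q.T @ Y.T)
        return (resid**2).sum(axis=0), np.linalg.matrix_rank(X)

    rss_full, rank_full = rss(X_full)
    rss_red, rank_red = rss(X_red)
    df_num = rank_full - rank_red
    df_den = n - rank_full
    ss_group = np.maximum(rss_red - rss_full, 0.0)
    scale = np.maximum((Y**2).sum(axis=1), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_group / df_num) / (rss_full / df_den)
    p = sps.f.sf(f_stat, df_num, df_den)
    degenerate = ss_group <= 1e-12 * scale
    f_stat = np.where(degenerate, 0.0, f_stat)
    p = np.where(degenerate, 1.0, p)
    exact = (rss_full <= 1e-12 * scale) & ~degenerate
    f_stat = np.where(exact, np.inf, f_stat)
    p = np.where(exact, 0.0, p)
    return f_stat, p


def stage2_radioresistance(
    expr: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    thresholds: FunnelThresholds | None = None,
) -> list[DEGeneResult]:
    """Radioresistant-vs-radiosensitive group effect pooled across timepoints."""
    thresholds = thresholds or FunnelThresholds()
    ann = {a.sample_id: a for a in annotations}
    sample_ids = [s for s in expr.sample_ids
                  if s in ann and ann[s].rr_label in ("radioresistant", "radiosensitive")]
    group = np.array([ann[s].rr_label for s in sample_ids])
    if pd.unique(group).size < 2:
        raise ValueError("both radioresistance groups must be present")
    block = np.array([ann[s].timepoint or "t0" for s in sample_ids])
    if pd.unique(block).size < 2:
        warnings.warn("single timepoint: falling back to one-way comparison",
                      stacklevel=2)
    genes = _testable_genes(expr)
    Y = expr.values.loc[genes, sample_ids].to_numpy()
    complete = ~np.isnan(Y).any(axis=1)
    f_stat = np.empty(len(genes))
    pvals = np.empty(len(genes))
    if complete.any():
        f_stat[complete], pvals[complete] = _stage2_f_vectorized(
            Y[complete], group, block)
    for i in np.where(~complete)[0]:
        res = anova_group_effect(Y[i], group, block)
        f_stat[i], pvals[i] = res.statistic, res.p_value
    rr_mask = group == "radioresistant"
    lin = 2.0**Y
    fcs = []
    for i in range(len(genes)):
        row = lin[i]
        ok = np.isfinite(row)
        fcs.append(signed_fold_change(
            float(np.mean(row[rr_mask & ok])), float(np.mean(row[~rr_mask & ok]))))
    return _de_results(genes, fcs, pvals, thresholds)


def stage2_timepoint_report(
    expr: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Per-timepoint unpaired rank-test companion table for selected genes."""
    ann = {a.sample_id: a for a in annotations}
    sample_ids = [s for s in expr.sample_ids
                  if s in ann and ann[s].rr_label in ("radioresistant", "radiosensitive")]
    rows = []
    timepoints = sorted({ann[s].timepoint or "t0" for s in sample_ids})
    for gene in genes:
        row: dict = {"gene": gene}
        for tp in timepoints:
            ids = [s for s in sample_ids if (ann[s].timepoint or "t0") == tp]
            rr = [expr.values.loc[gene, s] for s in ids
                  if ann[s].rr_label == "radioresistant"]
            rs = [expr.values.loc[gene, s] for s in ids
                  if ann[s].rr_label == "radiosensitive"]
            res = mann_whitney(rr, rs)
            row[f"fc_{tp}"] = signed_fold_change(
                float(np.mean(np.power(2.0, rr))), float(np.mean(np.power(2.0, rs))))
            row[f"p_{tp}"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def stage3_cox_screen(
    expr: ExpressionMatrix,
    survival: Sequence[SurvivalRecord],
    genes: Sequence[str],
    thresholds: FunnelThresholds | None = None,
    *,
    standardize: bool = False,
) -> list[CoxGeneResult]:
    """Per-gene multivariate Cox screen; retains genes with p < cox_p_max."""
    thresholds = thresholds or FunnelThresholds()
    in_matrix = set(expr.sample_ids)
    records = [r for r in survival if r.sample_id in in_matrix]
    if len(records) < 30:
        raise ValueError(f"survival cohort too small ({len(records)} < 30)")
    if sum(r.event for r in records) < 10:
        raise ValueError("fewer than 10 events in survival cohort")
    sample_ids = [r.sample_id for r in records]
    age = [r.age for r in records]
    node = [r.node_stage for r in records]
    stage = [r.tumor_stage for r in records]
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"candidate genes absent from matrix: {missing[:10]}")
    retained = []
    for gene in genes:
        vec = expr.values.loc[gene, sample_ids].to_numpy(float)
        if np.ptp(vec[np.isfinite(vec)]) == 0:
            warnings.warn(f"gene {gene} constant across cohort; excluded", stacklevel=2)
            continue
        if standardize:
            vec = (vec - np.nanmean(vec)) / np.nanstd(vec)
        try:
            fit = cox_fit(records, {"expr": vec, "age": age,
                                    "node_stage": node, "tumor_stage": stage})
        except ValidationError as exc:
            warnings.warn(f"gene {gene} excluded: {exc}", stacklevel=2)
            continue
        if not fit.converged:
            warnings.warn(f"gene {gene}: Cox fit did not converge; excluded",
                          stacklevel=2)
            continue
        if fit.p_values["expr"] < thresholds.cox_p_max:
            retained.append(CoxGeneResult(gene, fit.hazard_ratio("expr"),
                                          fit.p_values["expr"]))
    return sorted(retained, key=lambda r: r.gene)


def select_signature(
    s1: Sequence[DEGeneResult],
    s2: Sequence[DEGeneResult],
    s3: Sequence[CoxGeneResult],
    *,
    concordance: bool = True,
    name: str = "RadR",
) -> SignatureGeneSet | None:
    """Intersect the three stage outputs into a directional signature.

    With ``concordance`` (default) a gene must have the same direction in
    stages 1 and 2; the output direction follows stage 1.  Returns None with
    a warning when the intersection is empty.
    """
    d1 = {r.gene: r.direction for r in s1}
    d2 = {r.gene: r.direction for r in s2}
    g3 = {r.gene for r in s3}
    common = sorted(set(d1) & set(d2) & g3)
    if concordance:
        common = [g for g in common if d1[g] == d2[g]]
    if not common:
        warnings.warn("empty signature: no gene passed all three stages", stacklevel=2)
        return None
    up = frozenset(g for g in common if d1[g] == "UP")
    dn = frozenset(g for g in common if d1[g] == "DN")
    return SignatureGeneSet(name, up, dn)


def funnel_table(
    s1: Sequence[DEGeneResult],
    s2: Sequence[DEGeneResult],
    s3: Sequence[CoxGeneResult],
    signature: SignatureGeneSet | None,
) -> pd.DataFrame:
    """Signature summary table (gene, direction, fc/fdr per stage, hr, p)."""
    d1 = {r.gene: r for r in s1}
    d2 = {r.gene: r for r in s2}
    d3 = {r.gene: r for r in s3}
    rows = []
    for gene in sorted(signature.all_genes if signature else []):
        rows.append({
            "gene": gene,
            "direction": "UP" if signature and gene in signature.up_genes else "DN",
            "fc_s1": d1[gene].fc, "fdr_s1": d1[gene].fdr,
            "fc_s2": d2[gene].fc, "fdr_s2": d2[gene].fdr,
            "hr": d3[gene].hr, "p": d3[gene].p_value,
        })
    return pd.DataFrame(
        rows, columns=["gene", "direction", "fc_s1", "fdr_s1",
                       "fc_s2", "fdr_s2", "hr", "p"])


# ---------------------------------------------------------------------------
# Packaged 13-gene signature table and replay mode


def _parse_bounded(val: str) -> float:
    """Parse a printed p-value; '<x' is read as its upper bound x."""
    s = str(val).strip()
    return float(s[1:]) if s.startswith("<") else float(s)


def load_signature_table() -> pd.DataFrame:
    """The packaged 13-row signature table (FC/FDR per comparison, HR, P)."""
    with resources.files("radr.data").joinpath("signature_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("fc_tumor_vs_normal", "fdr_tumor_vs_normal",
                "fc_rr_vs_rs", "fdr_rr_vs_rs", "hr", "p_value"):
        df[col] = df[col].map(_parse_bounded)
    return df


def replay_signature(
    table: pd.DataFrame | None = None,
    thresholds: FunnelThresholds | None = None,
    *,
    concordance: bool = True,
    name: str = "RadR",
) -> tuple[SignatureGeneSet | None, pd.DataFrame]:
    """Feed a printed stage-results table back through the selection logic.

    Each row carries the per-stage statistics; rows are turned into stage
    outputs wherever they satisfy that stage's own filter, and the stage
    outputs are intersected exactly as in a live run.
    """
    thresholds = thresholds or FunnelThresholds()
    df = table if table is not None else load_signature_table()
    s1, s2, s3 = [], [], []
    for _, row in df.iterrows():
        fc1, fdr1 = row["fc_tumor_vs_normal"], row["fdr_tumor_vs_normal"]
        if fdr1 < thresholds.fdr_max and abs(fc1) > thresholds.abs_fc_min:
            s1.append(DEGeneResult(row["gene"], fc1, fdr1, fdr1,
                                   "UP" if fc1 > 0 else "DN"))
        fc2, fdr2 = row["fc_rr_vs_rs"], row["fdr_rr_vs_rs"]
        if fdr2 < thresholds.fdr_max and abs(fc2) > thresholds.abs_fc_min:
            s2.append(DEGeneResult(row["gene"], fc2, fdr2, fdr2,
                                   "UP" if fc2 > 0 else "DN"))
        if row["p_value"] < thresholds.cox_p_max:
            s3.append(CoxGeneResult(row["gene"], row["hr"], row["p_value"]))
    sig = select_signature(s1, s2, s3, concordance=concordance, name=name)
    return sig, funnel_table(s1, s2, s3, sig)


def packaged_signature() -> SignatureGeneSet:
    """The 13-gene signature obtained by replaying the packaged table."""
    sig, _ = replay_signature()
    assert sig is not None
    return sig
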