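"""End-to-end orchestration: the discovery funnel and the validation battery.

Both entry points operate on in-memory domain objects; the CLI layer wires
files to them and records a manifest (input hashes, seed, thresholds) so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    ScoreTable,
    SignatureGeneSet,
    SurvivalRecord,
)
from .integration import (
    compare_groups,
    correlate_with_matrix,
    median_split_survival,
)
from .io import write_signature_gmt
from .selection import (
    FunnelThresholds,
    funnel_table,
    select_signature,
    stage1_tumor_vs_normal,
    stage2_radioresistance,
    stage2_timepoint_report,
    stage3_cox_screen,
)
from .ssgsea import SsgseaParams, score_collection, score_signature
from .stats import paired_wilcoxon

logger = logging.getLogger("radr")


@dataclass
class DiscoveryBundle:
    paired_expr: ExpressionMatrix
    paired_ann: Sequence[SampleAnnotation]
    cell_expr: ExpressionMatrix
    cell_ann: Sequence[SampleAnnotation]
    surv_expr: ExpressionMatrix
    surv_records: Sequence[SurvivalRecord]


@dataclass
class DiscoveryReport:
    signature: Optional[SignatureGeneSet]
    stage_counts: dict[str, int]
    table: pd.DataFrame
    timepoint_report: pd.DataFrame


def run_discovery(
    bundle: DiscoveryBundle,
    thresholds: FunnelThresholds | None = None,
    *,
    concordance: bool = True,
    name: str = "RadR",
    out_dir: Optional[Path] = None,
) -> DiscoveryReport:
    """Run stage1 -> stage2 -> stage3 -> intersection."""
    thresholds = thresholds or FunnelThresholds()
    logger.info("stage 1: paired tumor-vs-normal differential expression")
    s1 = stage1_tumor_vs_normal(bundle.paired_expr, bundle.paired_ann, thresholds)
    logger.info("stage 1 selected %d genes", len(s1))
    logger.info("stage 2: radioresistant-vs-radiosensitive cell lines")
    s2 = stage2_radioresistance(bundle.cell_expr, bundle.cell_ann, thresholds)
    logger.info("stage 2 selected %d genes", len(s2))
    candidates = sorted({r.gene for r in s1} & {r.gene for r in s2})
    logger.info("stage 3: Cox screen on %d candidate genes", len(candidates))
    s3 = stage3_cox_screen(bundle.surv_expr, bundle.surv_records, candidates,
                           thresholds) if candidates else []
    signature = select_signature(s1, s2, s3, concordance=concordance, name=name)
    table = funnel_table(s1, s2, s3, signature)
    tp_report = stage2_timepoint_report(
        bundle.cell_expr, bundle.cell_ann,
        sorted(signature.all_genes) if signature else [])
    report = DiscoveryReport(
        signature=signature,
        stage_counts={"stage1": len(s1), "stage2": len(s2),
                      "stage3": len(s3),
                      "signature": len(signature) if signature else 0},
        table=table,
        timepoint_report=tp_report,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "signature_table.tsv", sep="\t", index=False,
                     float_format="%.6g")
        tp_report.to_csv(out_dir / "stage2_timepoints.tsv", sep="\t", index=False,
                         float_format="%.6g")
        with open(out_dir / "stage_counts.json", "w") as fh:
            json.dump(report.stage_counts, fh, indent=2)
        if signature is not None:
            write_signature_gmt(signature, out_dir / "signature.gmt")
    return report


@dataclass
class ValidationDataset:
    name: str
    expression: ExpressionMatrix
    annotations: Optional[Sequence[SampleAnnotation]] = None
    survival: Optional[Sequence[SurvivalRecord]] = None
    hallmark_sets: Optional[GeneSetCollection] = None
    proteins: Optional[pd.DataFrame] = None
    ic50: Optional[pd.DataFrame] = None


@dataclass
class ValidationReport:
    summary: pd.DataFrame
    scores: dict[str, ScoreTable]
    details: dict[str, object] = field(default_factory=dict)


def run_validation(
    signature: SignatureGeneSet,
    datasets: Sequence[ValidationDataset],
    params: SsgseaParams | None = None,
    *,
    screen_r_min: float = 0.2,
    screen_p_max: float = 0.01,
    out_dir: Optional[Path] = None,
) -> ValidationReport:
    """Score each dataset and run every applicable downstream analysis.

    Analyses whose required annotations are missing are skipped with a
    logged warning, never silently.
    """
    params = params or SsgseaParams()
    rows: list[dict] = []
    all_scores: dict[str, ScoreTable] = {}
    details: dict[str, object] = {}

    def add(dataset: str, analysis: str, statistic: float, p: float, note: str = ""):
        rows.append({"dataset": dataset, "analysis": analysis,
                     "statistic": statistic, "p_value": p, "note": note})

    def skip(dataset: str, analysis: str, reason: str):
        logger.warning("%s: %s skipped: %s", dataset, analysis, reason)

    for ds in datasets:
        scores = score_signature(ds.expression, signature, params)
        all_scores[ds.name] = scores
        ann = {a.sample_id: a for a in (ds.annotations or [])}

        # paired tumor-vs-normal score comparison
        pairs = {}
        for a in (ds.annotations or []):
            if a.pair_id:
                pairs.setdefault(a.pair_id, {})[a.tissue] = a.sample_id
        complete = [(v["tumor"], v["normal"]) for v in pairs.values()
                    if set(v) == {"tumor", "normal"}]
        if len(complete) >= 2:
            t = [scores[t_id] for t_id, _ in complete]
            n = [scores[n_id] for _, n_id in complete]
            res = paired_wilcoxon(t, n)
            add(ds.name, "paired_tumor_vs_normal", res.statistic, res.p_value,
                f"{len(complete)} pairs")
        else:
            skip(ds.name, "paired_tumor_vs_normal", "no tumor/normal pairs")

        # radioresistance group comparison
        rr_labels = {s: a.rr_label for s, a in ann.items()
                     if a.rr_label in ("radioresistant", "radiosensitive")}
        if len(set(rr_labels.values())) == 2:
            res = compare_groups(scores, rr_labels)
            add(ds.name, "rr_group_comparison", res.test.statistic,
                res.test.p_value, json.dumps(res.medians))
        else:
            skip(ds.name, "rr_group_comparison", "no radioresistance labels")

        # median-split survival
        if ds.survival:
            try:
                strat = median_split_survival(scores, ds.survival)
                add(ds.name, "median_split_survival", strat.logrank.statistic,
                    strat.logrank.p_value,
                    f"split={strat.split_value:.4g} sizes={strat.group_sizes}")
                details[f"{ds.name}/median_split"] = strat
            except ValueError as exc:
                skip(ds.name, "median_split_survival", str(exc))
        else:
            skip(ds.name, "median_split_survival", "no survival table")

        # subtype / HPV / genotype comparisons
        for analysis, mapping in (
            ("subtype_comparison", {s: a.subtype for s, a in ann.items() if a.subtype}),
            ("hpv_comparison", {s: a.hpv_status for s, a in ann.items() if a.hpv_status}),
        ):
            if len(set(mapping.values())) >= 2:
                res = compare_groups(scores, mapping)
                add(ds.name, analysis, res.test.statistic, res.test.p_value,
                    json.dumps(res.medians))
            else:
                skip(ds.name, analysis, "fewer than 2 labelled groups")
        flag_genes = sorted({g for a in ann.values() for g in a.genotype_flags})
        for gene in flag_genes:
            mapping = {s: a.genotype_flags[gene] for s, a in ann.items()
                       if gene in a.genotype_flags}
            if len(set(mapping.values())) == 2:
                res = compare_groups(scores, mapping)
                add(ds.name, f"genotype_{gene}", res.test.statistic,
                    res.test.p_value, json.dumps(res.medians))
            else:
                skip(ds.name, f"genotype_{gene}", "only one genotype present")

        # correlation screens
        if ds.hallmark_sets is not None:
            es = score_collection(ds.expression, ds.hallmark_sets, params)
            screen = correlate_with_matrix(scores, es, r_min=screen_r_min,
                                           p_max=screen_p_max, sign="any")
            add(ds.name, "hallmark_screen", float(len(screen.hits)), float("nan"),
                "hits: " + ",".join(screen.hits))
            details[f"{ds.name}/hallmark_screen"] = screen
        if ds.proteins is not None:
            screen = correlate_with_matrix(scores, ds.proteins, r_min=screen_r_min,
                                           p_max=screen_p_max, sign="any")
            add(ds.name, "protein_screen", float(len(screen.hits)), float("nan"),
                "hits: " + ",".join(screen.hits))
            details[f"{ds.name}/protein_screen"] = screen
        if ds.ic50 is not None:
            screen = correlate_with_matrix(scores, ds.ic50, r_min=screen_r_min,
                                           p_max=screen_p_max, sign="positive")
            add(ds.name, "drug_screen", float(len(screen.hits)), float("nan"),
                "hits: " + ",".join(screen.hits))
            details[f"{ds.name}/drug_screen"] = screen

    summary = pd.DataFrame(rows, columns=["dataset", "analysis", "statistic",
                                          "p_value", "note"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "validation_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
        for key, obj in details.items():
            if hasattr(obj, "table"):
                fname = key.replace("/", "__") + ".tsv"
                obj.table.to_csv(out_dir / fname, sep="\t", index=False,
                                 float_format="%.6g")
    return ValidationReport(summary=summary, scores=all_scores, details=details)


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, *, inputs: dict[str, Path],
                   seed: Optional[int] = None, **settings) -> Path:
    """Machine-readable record of a run: input hashes, seed, settings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "radr_version": __version__,
        "seed": seed,
        "inputs": {name: {"path": str(p), "sha256": sha256_of(Path(p))}
                   for name, p in inputs.items()},
        "settings": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                         else str(v)) for k, v in settings.items()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
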