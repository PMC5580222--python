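"""Synthetic cohort generators with known ground truth.

Every generator draws from ``numpy.random.default_rng`` (PCG64) seeded
explicitly, so identical (config, seed) pairs yield identical datasets on
any platform.  Expression is log-normal on log2 scale (baseline N(8, 2) per
gene) with additive planted effects — sufficient for the rank- and
ratio-based selection stages.

Planted structure:

* paired cohort — tumor samples of planted genes shifted by +/- log2(de_fc);
* cell-line panel — planted genes shifted by +/- log2(rr_fc) in
  radioresistant lines at every timepoint, with a nuisance timepoint main
  effect on a random 10% of null genes; SF2 values honor the < 0.2 / > 0.8
  labelling rule;
* survival cohort — a latent per-sample radioresistance score drives both
  expression (planted genes load on it with opposite signs) and the event
  hazard, exp(log_hr_per_unit x latent); the latent factor loading is what
  gives each planted gene a recoverable marginal hazard signal;
* feature panels — 48 hallmark-style sets (one built from latent-loaded
  genes), a protein panel with one feature tracking planted up-gene
  expression, and 140 IC50 vectors of which exactly ``n_planted_drugs``
  correlate with the latent score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    SurvivalRecord,
)
from .errors import ValidationError

DEFAULT_SUBTYPE_SHIFTS = {
    "atypical": -1.0,
    "basal": 0.0,
    "classical": 0.0,
    "mesenchymal": 1.0,
}


@dataclass
class GeneratorConfig:
    n_genes: int = 2000
    n_pairs: int = 40
    n_lines: int = 32
    n_rr: int = 18
    n_patients: int = 300
    planted_up: int = 3
    planted_dn: int = 10
    de_fc: float = 4.0
    rr_fc: float = 2.0
    log_hr_per_unit: float = 0.5
    noise_sd: float = 1.0
    cellline_noise_sd: float = 0.5
    censor_rate: float = 0.4
    latent_loading: float = 0.8
    hallmark_loading: float = 0.5
    subtype_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_SHIFTS))
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    median_survival_months: float = 24.0
    n_hallmark_sets: int = 48
    hallmark_set_size: int = 25
    n_hallmark_genes: int = 25
    n_drugs: int = 140
    n_planted_drugs: int = 4
    n_drug_lines: int = 659
    drug_true_r: float = 0.5
    n_proteins: int = 188

    def validate(self) -> None:
        problems = []
        if self.planted_up + self.planted_dn + self.n_hallmark_genes > self.n_genes:
            problems.append("planted_up + planted_dn + n_hallmark_genes > n_genes")
        for name in ("n_genes", "n_pairs", "n_lines", "n_patients", "n_drugs",
                     "n_drug_lines", "n_proteins", "n_hallmark_sets"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if not (0 < self.n_rr < self.n_lines):
            problems.append("n_rr must lie strictly between 0 and n_lines")
        if not (0 <= self.censor_rate < 1):
            problems.append("censor_rate must lie in [0, 1)")
        if self.de_fc < 1 or self.rr_fc < 1:
            problems.append("de_fc and rr_fc must be >= 1")
        if self.noise_sd <= 0 or self.cellline_noise_sd <= 0:
            problems.append("noise sds must be positive")
        if self.n_planted_drugs > self.n_drugs:
            problems.append("n_planted_drugs > n_drugs")
        if problems:
            raise ValidationError("invalid generator config: " + "; ".join(problems))

    # planted gene identities are a pure function of the config so that the
    # paired, cell-line and survival cohorts plant the same genes
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def planted_up_genes(self) -> list[str]:
        return self.gene_ids()[: self.planted_up]

    def planted_dn_genes(self) -> list[str]:
        g = self.gene_ids()
        return g[self.planted_up: self.planted_up + self.planted_dn]

    def hallmark_genes(self) -> list[str]:
        g = self.gene_ids()
        start = self.planted_up + self.planted_dn
        return g[start: start + self.n_hallmark_genes]


@dataclass
class SyntheticTruth:
    up_genes: list[str]
    dn_genes: list[str]
    effects: dict[str, float]
    latent: Optional[dict[str, float]] = None
    nuisance_genes: list[str] = field(default_factory=list)
    hallmark_set: Optional[str] = None
    hallmark_genes: list[str] = field(default_factory=list)
    planted_drugs: list[str] = field(default_factory=list)
    planted_proteins: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "up_genes": self.up_genes, "dn_genes": self.dn_genes,
            "effects": self.effects, "latent": self.latent,
            "nuisance_genes": self.nuisance_genes,
            "hallmark_set": self.hallmark_set,
            "hallmark_genes": self.hallmark_genes,
            "planted_drugs": self.planted_drugs,
            "planted_proteins": self.planted_proteins,
        }


def _baseline(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene baseline expression.

    Planted and hallmark genes are drawn with a tight spread around the
    cohort mean so their within-sample ranks stay responsive to planted
    effects instead of being pinned to the extremes by a lucky baseline.
    """
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    n_structured = cfg.planted_up + cfg.planted_dn + cfg.n_hallmark_genes
    baseline[:n_structured] = rng.normal(cfg.baseline_mean, 0.5, n_structured)
    return baseline


def _planted_shift(cfg: GeneratorConfig, fc: float) -> np.ndarray:
    shift = np.zeros(cfg.n_genes)
    delta = np.log2(fc)
    shift[: cfg.planted_up] = delta
    shift[cfg.planted_up: cfg.planted_up + cfg.planted_dn] = -delta
    return shift


def _latent_loadings(cfg: GeneratorConfig) -> np.ndarray:
    load = np.zeros(cfg.n_genes)
    load[: cfg.planted_up] = cfg.latent_loading
    load[cfg.planted_up: cfg.planted_up + cfg.planted_dn] = -cfg.latent_loading
    start = cfg.planted_up + cfg.planted_dn
    load[start: start + cfg.n_hallmark_genes] = cfg.hallmark_loading
    return load


def generate_paired_cohort(
    cfg: GeneratorConfig, seed: int,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Paired tumor/normal cohort with planted up/down genes."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    genes = cfg.gene_ids()
    baseline = _baseline(cfg, rng)
    shift = _planted_shift(cfg, cfg.de_fc)
    cols, annotations = {}, []
    for i in range(1, cfg.n_pairs + 1):
        pair = f"P{i:03d}"
        for tissue, prefix, offset in (("tumor", "T", shift), ("normal", "N", 0.0)):
            sid = f"{prefix}{i:03d}"
            cols[sid] = baseline + offset + rng.normal(0, cfg.noise_sd, cfg.n_genes)
            annotations.append(SampleAnnotation(sid, tissue, pair_id=pair))
    expr = ExpressionMatrix(pd.DataFrame(cols, index=genes))
    truth = SyntheticTruth(
        up_genes=cfg.planted_up_genes(), dn_genes=cfg.planted_dn_genes(),
        effects={"de_fc": cfg.de_fc},
    )
    return expr, annotations, truth


def generate_cellline_panel(
    cfg: GeneratorConfig, seed: int,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Cell-line panel measured at three post-irradiation timepoints."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    genes = cfg.gene_ids()
    timepoints = ("t0", "t2h", "t6h")
    baseline = _baseline(cfg, rng)
    rr_shift = _planted_shift(cfg, cfg.rr_fc)

    n_planted = cfg.planted_up + cfg.planted_dn
    null_idx = np.arange(n_planted, cfg.n_genes)
    n_nuisance = max(1, int(round(0.1 * cfg.n_genes)))
    nuisance_idx = rng.choice(null_idx, size=min(n_nuisance, null_idx.size),
                              replace=False)
    tp_delta = np.zeros(cfg.n_genes)
    tp_delta[nuisance_idx] = rng.uniform(0.5, 1.5, nuisance_idx.size)
    tp_sign = {"t0": 0.0, "t2h": 1.0, "t6h": -1.0}

    cols, annotations = {}, []
    for i in range(1, cfg.n_lines + 1):
        line = f"L{i:02d}"
        is_rr = i <= cfg.n_rr
        sf2 = rng.uniform(0.82, 0.95) if is_rr else rng.uniform(0.05, 0.18)
        label = "radioresistant" if is_rr else "radiosensitive"
        for tp in timepoints:
            sid = f"{line}_{tp}"
            cols[sid] = (
                baseline
                + (rr_shift if is_rr else 0.0)
                + tp_sign[tp] * tp_delta
                + rng.normal(0, cfg.cellline_noise_sd, cfg.n_genes)
            )
            annotations.append(SampleAnnotation(
                sid, "cell_line", rr_label=label, sf2=float(sf2), timepoint=tp,
                extra={"line": line}))
    expr = ExpressionMatrix(pd.DataFrame(cols, index=genes))
    truth = SyntheticTruth(
        up_genes=cfg.planted_up_genes(), dn_genes=cfg.planted_dn_genes(),
        effects={"rr_fc": cfg.rr_fc},
        nuisance_genes=[genes[j] for j in sorted(nuisance_idx)],
    )
    return expr, annotations, truth


def generate_survival_cohort(
    cfg: GeneratorConfig, seed: int,
) -> tuple[ExpressionMatrix, list[SurvivalRecord], list[SampleAnnotation], SyntheticTruth]:
    """Tumor cohort whose event hazard increases with a latent score.

    The latent per-sample score drives planted-gene expression (loading
    +/- latent_loading) and the exponential event hazard; subtype labels add
    their configured shift to the latent score.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    genes = cfg.gene_ids()
    subtype_names = sorted(cfg.subtype_shifts)
    baseline = _baseline(cfg, rng)
    shift = _planted_shift(cfg, cfg.de_fc)
    load = _latent_loadings(cfg)
    lam0 = np.log(2.0) / cfg.median_survival_months

    cols, annotations, records = {}, [], []
    latent_map: dict[str, float] = {}
    for i in range(1, cfg.n_patients + 1):
        sid = f"S{i:04d}"
        subtype = subtype_names[rng.integers(len(subtype_names))]
        latent = float(rng.normal() + cfg.subtype_shifts[subtype])
        latent_map[sid] = latent
        cols[sid] = (baseline + shift + load * latent
                     + rng.normal(0, cfg.noise_sd, cfg.n_genes))
        age = float(np.clip(rng.normal(61, 10), 30, 90))
        node = int(rng.integers(0, 2))
        stage = int(rng.integers(0, 2))
        lam = lam0 * np.exp(cfg.log_hr_per_unit * latent
                            + 0.3 * node + 0.3 * stage + 0.01 * (age - 61))
        t_event = rng.exponential(1.0 / lam)
        if cfg.censor_rate > 0:
            lam_c = lam0 * cfg.censor_rate / (1.0 - cfg.censor_rate)
            t_cens = rng.exponential(1.0 / lam_c)
        else:
            t_cens = np.inf
        time = max(float(min(t_event, t_cens)), 0.01)
        event = int(t_event <= t_cens)
        alt_a = rng.random() < 0.5 / (1.0 + np.exp(-latent))
        alt_b = rng.random() < 0.25
        annotations.append(SampleAnnotation(
            sid, "tumor", subtype=subtype, hpv_status="negative",
            genotype_flags={
                "GENE_A": "altered" if alt_a else "wild_type",
                "GENE_B": "altered" if alt_b else "wild_type",
            }))
        records.append(SurvivalRecord(sid, time, event, age=age,
                                      node_stage=node, tumor_stage=stage))
    expr = ExpressionMatrix(pd.DataFrame(cols, index=genes))
    truth = SyntheticTruth(
        up_genes=cfg.planted_up_genes(), dn_genes=cfg.planted_dn_genes(),
        effects={"log_hr_per_unit": cfg.log_hr_per_unit,
                 "latent_loading": cfg.latent_loading},
        latent=latent_map,
        hallmark_genes=cfg.hallmark_genes(),
    )
    return expr, records, annotations, truth


@dataclass
class FeaturePanelBundle:
    expression: ExpressionMatrix
    annotations: list[SampleAnnotation]
    hallmark_sets: GeneSetCollection
    proteins: pd.DataFrame  # protein x sample
    ic50: pd.DataFrame      # drug x sample
    truth: SyntheticTruth


def generate_feature_panels(cfg: GeneratorConfig, seed: int) -> FeaturePanelBundle:
    """Cell-line panel with hallmark sets, protein and IC50 matrices.

    Exactly ``n_planted_drugs`` IC50 vectors correlate with the latent score
    (true r = drug_true_r); one hallmark set is built from latent-loaded
    genes; one protein tracks mean planted up-gene expression.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    genes = cfg.gene_ids()
    baseline = _baseline(cfg, rng)
    shift = _planted_shift(cfg, cfg.de_fc)
    load = _latent_loadings(cfg)

    sample_ids = [f"C{i:04d}" for i in range(1, cfg.n_drug_lines + 1)]
    latent = rng.normal(size=cfg.n_drug_lines)
    noise = rng.normal(0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_drug_lines))
    values = baseline[:, None] + shift[:, None] + np.outer(load, latent) + noise
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    annotations = [SampleAnnotation(s, "cell_line") for s in sample_ids]

    # hallmark collection: set 1 is the planted, latent-loaded set
    planted_name = "HALLMARK_01"
    reserved = cfg.planted_up + cfg.planted_dn + cfg.n_hallmark_genes
    pool = np.array(genes[reserved:])
    sets: dict[str, list[str]] = {planted_name: cfg.hallmark_genes()}
    for k in range(2, cfg.n_hallmark_sets + 1):
        members = rng.choice(pool, size=min(cfg.hallmark_set_size, pool.size),
                             replace=False)
        sets[f"HALLMARK_{k:02d}"] = sorted(members.tolist())
    hallmarks = GeneSetCollection(sets)

    # IC50 panel: planted drugs correlate with the latent score at drug_true_r
    drug_names = [f"DRUG_{i:03d}" for i in range(1, cfg.n_drugs + 1)]
    planted_drugs = sorted(
        rng.choice(drug_names, size=cfg.n_planted_drugs, replace=False).tolist())
    rho = cfg.drug_true_r
    slope = rho / np.sqrt(1.0 - rho**2) if rho < 1 else 1e6
    ic50_rows = {}
    for name in drug_names:
        if name in planted_drugs:
            ic50_rows[name] = slope * latent + rng.normal(size=cfg.n_drug_lines)
        else:
            ic50_rows[name] = rng.normal(size=cfg.n_drug_lines)
    ic50 = pd.DataFrame(ic50_rows, index=sample_ids).T

    # protein panel: PROT_001 tracks mean planted up-gene expression
    protein_names = [f"PROT_{i:03d}" for i in range(1, cfg.n_proteins + 1)]
    up_mean = expr.values.loc[cfg.planted_up_genes()].mean(axis=0).to_numpy()
    prot_rows = {}
    for name in protein_names:
        if name == "PROT_001":
            prot_rows[name] = up_mean + rng.normal(0, 0.5, cfg.n_drug_lines)
        else:
            prot_rows[name] = rng.normal(size=cfg.n_drug_lines)
    proteins = pd.DataFrame(prot_rows, index=sample_ids).T

    truth = SyntheticTruth(
        up_genes=cfg.planted_up_genes(), dn_genes=cfg.planted_dn_genes(),
        effects={"drug_true_r": cfg.drug_true_r},
        latent=dict(zip(sample_ids, latent.tolist())),
        hallmark_set=planted_name, hallmark_genes=cfg.hallmark_genes(),
        planted_drugs=planted_drugs, planted_proteins=["PROT_001"],
    )
    return FeaturePanelBundle(expr, annotations, hallmarks, proteins, ic50, truth)
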