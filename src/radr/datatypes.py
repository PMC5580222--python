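"""Domain types: expression matrices, sample annotations, survival records,
gene signatures and score tables.

All expression values are stored on log2 scale internally.  Missing values
are represented as NaN and are dropped pairwise by downstream statistics;
infinities are rejected at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

TISSUES = frozenset({"tumor", "normal", "cell_line"})
RR_LABELS = frozenset({"radioresistant", "radiosensitive", "intermediate"})
TIMEPOINTS = frozenset({"t0", "t2h", "t6h"})
SUBTYPES = frozenset({"atypical", "basal", "classical", "mesenchymal"})
HPV_STATUSES = frozenset({"positive", "negative"})
GENOTYPES = frozenset({"altered", "wild_type"})


class ExpressionMatrix:
    """Genes x samples numeric table on log2 scale.

    Parameters
    ----------
    values
        DataFrame with gene symbols as index and sample identifiers as
        columns.  NaN marks missing measurements.
    linear
        If True the input is linear-scale and is converted with
        ``log2(x + 1)`` on load.
    """

    def __init__(self, values: pd.DataFrame, *, linear: bool = False):
        if not isinstance(values, pd.DataFrame):
            raise ValidationError("expression values must be a DataFrame")
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise ValidationError("expression matrix must be non-empty")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        vals = values.astype(float)
        if linear:
            if (vals < 0).any().any():
                raise ValidationError("linear-scale input contains negative values")
            vals = np.log2(vals + 1.0)
        arr = vals.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError("expression matrix contains infinite values")
        self.values = vals
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene(self, gene_id: str) -> pd.Series:
        return self.values.loc[gene_id]

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)])

    def linear(self) -> pd.DataFrame:
        """Values back-transformed to linear scale (2**x)."""
        return np.power(2.0, self.values)

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass
class SampleAnnotation:
    sample_id: str
    tissue: str
    pair_id: Optional[str] = None
    rr_label: Optional[str] = None
    sf2: Optional[float] = None
    auc: Optional[float] = None
    timepoint: Optional[str] = None
    subtype: Optional[str] = None
    hpv_status: Optional[str] = None
    genotype_flags: dict[str, str] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_id}: tissue {self.tissue!r} not in {sorted(TISSUES)}"
            )
        for attr, allowed in (
            ("rr_label", RR_LABELS),
            ("timepoint", TIMEPOINTS),
            ("subtype", SUBTYPES),
            ("hpv_status", HPV_STATUSES),
        ):
            val = getattr(self, attr)
            if val is not None and val not in allowed:
                raise ValidationError(
                    f"sample {self.sample_id}: {attr} {val!r} not in {sorted(allowed)}"
                )
        if self.sf2 is not None and not (0.0 <= self.sf2 <= 1.0):
            raise ValidationError(f"sample {self.sample_id}: sf2 {self.sf2} outside [0, 1]")
        if self.auc is not None and self.auc <= 0:
            raise ValidationError(f"sample {self.sample_id}: auc must be positive")
        for gene, status in self.genotype_flags.items():
            if status not in GENOTYPES:
                raise ValidationError(
                    f"sample {self.sample_id}: genotype flag {gene}={status!r} invalid"
                )


def validate_pairs(annotations: Iterable[SampleAnnotation]) -> dict[str, tuple[str, str]]:
    """Check tumor/normal pairing and return pair_id -> (tumor_id, normal_id).

    Each pair_id must be shared by exactly one tumor and one normal sample.
    """
    by_pair: dict[str, dict[str, str]] = {}
    for ann in annotations:
        if ann.pair_id is None:
            continue
        slot = by_pair.setdefault(ann.pair_id, {})
        if ann.tissue not in ("tumor", "normal"):
            raise ValidationError(
                f"pair {ann.pair_id}: sample {ann.sample_id} has tissue {ann.tissue!r}"
            )
        if ann.tissue in slot:
            raise ValidationError(
                f"pair {ann.pair_id}: more than one {ann.tissue} sample"
            )
        slot[ann.tissue] = ann.sample_id
    pairs = {}
    for pair_id, slot in by_pair.items():
        if set(slot) != {"tumor", "normal"}:
            raise ValidationError(
                f"pair {pair_id}: needs exactly one tumor and one normal sample, got {sorted(slot)}"
            )
        pairs[pair_id] = (slot["tumor"], slot["normal"])
    return pairs


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float
    event: int
    age: float = 0.0
    node_stage: int = 0
    tumor_stage: int = 0

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValidationError(f"sample {self.sample_id}: time must be > 0")
        if self.event not in (0, 1):
            raise ValidationError(f"sample {self.sample_id}: event must be 0 or 1")
        if not np.isfinite(self.age):
            raise ValidationError(f"sample {self.sample_id}: age must be finite")
        if self.node_stage not in (0, 1) or self.tumor_stage not in (0, 1):
            raise ValidationError(
                f"sample {self.sample_id}: stage covariates must be 0 or 1"
            )


def survival_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a DataFrame indexed by sample_id."""
    rows = [
        (r.sample_id, r.time, r.event, r.age, r.node_stage, r.tumor_stage)
        for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["sample_id", "time", "event", "age", "node_stage", "tumor_stage"]
    ).set_index("sample_id")
    if df.index.has_duplicates:
        raise ValidationError("duplicate sample_id in survival records")
    return df


@dataclass(frozen=True)
class SignatureGeneSet:
    """Directional gene signature: up-regulated and down-regulated members."""

    name: str
    up_genes: frozenset[str]
    dn_genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "dn_genes", frozenset(self.dn_genes))
        overlap = self.up_genes & self.dn_genes
        if overlap:
            raise ValidationError(f"genes in both UP and DN sets: {sorted(overlap)}")
        if not (self.up_genes | self.dn_genes):
            raise ValidationError("signature must contain at least one gene")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.up_genes | self.dn_genes

    def __len__(self) -> int:
        return len(self.all_genes)


class GeneSetCollection:
    """Ordered mapping set_name -> list of gene symbols."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        self.sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            genes = list(genes)
            if not name:
                raise ValidationError("gene set name must be non-empty")
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if name in self.sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            self.sets[name] = genes

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


class ScoreTable:
    """Per-sample enrichment scores."""

    def __init__(self, scores: Mapping[str, float] | pd.Series):
        series = pd.Series(dict(scores), dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
        if series.empty:
            raise ValidationError("score table must be non-empty")
        if series.index.has_duplicates:
            raise ValidationError("duplicate sample ids in score table")
        if not np.isfinite(series.to_numpy()).all():
            raise ValidationError("scores must be finite")
        self.scores = series
        self.scores.index = self.scores.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def __getitem__(self, sample_id: str) -> float:
        return float(self.scores[sample_id])

    def __len__(self) -> int:
        return len(self.scores)
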