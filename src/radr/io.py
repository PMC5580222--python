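"""Readers and writers for GCT 1.2, GMT, clinical CSV/TSV and score tables.

Readers validate eagerly and raise :class:`~radr.errors.FormatError` /
:class:`~radr.errors.SchemaError` naming the offending file, line or sample
rather than silently coercing malformed records.  Floats are written with six
significant digits so that write-read round trips are stable.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    ScoreTable,
    SignatureGeneSet,
    SurvivalRecord,
)
from .errors import FormatError, SchemaError

PathLike = Union[str, Path]

_FLOAT_FMT = "%.6g"

ANNOTATION_COLUMNS = {
    "sample_id": str,
    "tissue": str,
    "pair_id": str,
    "rr_label": str,
    "sf2": float,
    "auc": float,
    "timepoint": str,
    "subtype": str,
    "hpv_status": str,
}

SURVIVAL_COLUMNS = ["sample_id", "time", "event", "age", "node_stage", "tumor_stage"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# GCT 1.2


def read_gct(path: PathLike, *, linear: bool = False) -> ExpressionMatrix:
    """Read a GCT 1.2 expression file.

    Duplicate gene symbols are collapsed to the row with the largest mean
    expression.  ``linear=True`` log2(x+1)-transforms values on load.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GCT file ({len(lines)} lines)")
    if lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: line 1: expected version '#1.2', got {lines[0]!r}")
    dims = lines[1].split("\t")
    if len(dims) != 2:
        raise FormatError(f"{path}: line 2: expected '<n_genes>\\t<n_samples>'")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2: non-integer dimensions {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise FormatError(f"{path}: line 3: header must start with 'Name\\tDescription'")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: declared {n_samples} samples but header has {len(sample_ids)}"
        )
    body = [ln for ln in lines[3:] if ln.strip() != ""]
    if len(body) != n_genes:
        raise FormatError(f"{path}: declared {n_genes} rows but found {len(body)}")
    genes, data = [], []
    for i, ln in enumerate(body, start=4):
        fields = ln.split("\t")
        if len(fields) != 2 + n_samples:
            raise FormatError(
                f"{path}: line {i}: expected {2 + n_samples} fields, got {len(fields)}"
            )
        genes.append(fields[0])
        row = []
        for tok in fields[2:]:
            if tok == "" or tok.upper() in ("NA", "NAN"):
                row.append(math.nan)
            else:
                try:
                    row.append(float(tok))
                except ValueError as exc:
                    raise FormatError(f"{path}: line {i}: bad value {tok!r}") from exc
        data.append(row)
    df = pd.DataFrame(data, index=genes, columns=sample_ids, dtype=float)
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        keep = (
            pd.DataFrame({"gene": df.index, "mean": means.to_numpy(), "pos": range(len(df))})
            .sort_values(["gene", "mean"], kind="mergesort")
            .groupby("gene", sort=False)["pos"]
            .last()
        )
        df = df.iloc[sorted(keep.to_numpy())]
    return ExpressionMatrix(df, linear=linear)


def write_gct(expr: ExpressionMatrix, path: PathLike,
              descriptions: Optional[dict[str, str]] = None) -> None:
    path = Path(path)
    df = expr.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(df.columns) + "\n")
        for gene, row in df.iterrows():
            desc = (descriptions or {}).get(gene, "na")
            vals = "\t".join(
                "NA" if not np.isfinite(v) else _FLOAT_FMT % v for v in row.to_numpy()
            )
            fh.write(f"{gene}\t{desc}\t{vals}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: PathLike) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if ln.strip() == "":
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {i}: expected name, description and >= 1 gene"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g != ""]
            if not genes:
                raise FormatError(f"{path}: line {i}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}: line {i}: duplicate gene set {name!r}")
            sets[name] = genes
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: PathLike,
              descriptions: Optional[dict[str, str]] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


def write_signature_gmt(sig: SignatureGeneSet, path: PathLike) -> None:
    """Write a directional signature as two sets ``<name>_UP`` / ``<name>_DN``."""
    sets: dict[str, list[str]] = {}
    if sig.up_genes:
        sets[f"{sig.name}_UP"] = sorted(sig.up_genes)
    if sig.dn_genes:
        sets[f"{sig.name}_DN"] = sorted(sig.dn_genes)
    write_gmt(GeneSetCollection(sets), path)


def read_signature_gmt(path: PathLike, name: Optional[str] = None) -> SignatureGeneSet:
    """Read a signature written by :func:`write_signature_gmt`.

    Sets ending in ``_UP`` / ``_DN`` are mapped to the respective side; a set
    with neither suffix is treated as UP.
    """
    coll = read_gmt(path)
    up: set[str] = set()
    dn: set[str] = set()
    base = None
    for set_name, genes in coll.items():
        if set_name.endswith("_UP"):
            up.update(genes)
            base = base or set_name[:-3]
        elif set_name.endswith("_DN"):
            dn.update(genes)
            base = base or set_name[:-3]
        else:
            up.update(genes)
            base = base or set_name
    return SignatureGeneSet(name or base or "signature", frozenset(up), frozenset(dn))


# ---------------------------------------------------------------------------
# Clinical tables


def _parse_optional(val, caster, column, sample_id, path):
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return None
    try:
        return caster(val)
    except (ValueError, TypeError) as exc:
        raise SchemaError(
            f"{path}: sample {sample_id}: cannot parse {column}={val!r}"
        ) from exc


def read_clinical(path: PathLike, schema: str) -> list:
    """Read a clinical CSV/TSV.

    ``schema='annotation'`` returns :class:`SampleAnnotation` records
    (required columns: ``sample_id, tissue``); ``schema='survival'`` returns
    :class:`SurvivalRecord` records (required: ``sample_id, time, event``).
    Unknown columns are preserved in ``extra`` for annotations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if schema == "annotation":
        required = ["sample_id", "tissue"]
    elif schema == "survival":
        required = ["sample_id", "time", "event"]
    else:
        raise ValueError(f"unknown schema {schema!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records = []
    if schema == "survival":
        for _, row in df.iterrows():
            sid = row["sample_id"]
            time = _parse_optional(row["time"], float, "time", sid, path)
            event_raw = row["event"]
            if event_raw not in ("0", "1", 0, 1):
                raise SchemaError(f"{path}: sample {sid}: event={event_raw!r} must be 0 or 1")
            kwargs = {}
            for col, caster in (("age", float), ("node_stage", int), ("tumor_stage", int)):
                if col in df.columns:
                    val = _parse_optional(row[col], caster, col, sid, path)
                    if val is not None:
                        kwargs[col] = val
            if time is None:
                raise SchemaError(f"{path}: sample {sid}: time is missing")
            records.append(SurvivalRecord(sid, time, int(event_raw), **kwargs))
        return records

    known = set(ANNOTATION_COLUMNS)
    for _, row in df.iterrows():
        sid = row["sample_id"]
        kwargs = {}
        for col, caster in ANNOTATION_COLUMNS.items():
            if col in ("sample_id", "tissue") or col not in df.columns:
                continue
            val = _parse_optional(row[col], caster, col, sid, path)
            if val is not None:
                kwargs[col] = val
        genotype_flags = {}
        extra = {}
        for col in df.columns:
            if col in known:
                continue
            val = row[col]
            if isinstance(val, float) and math.isnan(val):
                continue
            if col.startswith("genotype_"):
                genotype_flags[col[len("genotype_"):]] = val
            else:
                extra[col] = val
        records.append(
            SampleAnnotation(
                sample_id=sid, tissue=row["tissue"],
                genotype_flags=genotype_flags, extra=extra, **kwargs,
            )
        )
    return records


def write_annotations(annotations: Iterable[SampleAnnotation], path: PathLike) -> None:
    path = Path(path)
    rows = []
    flag_genes = sorted({g for a in annotations for g in a.genotype_flags})
    for a in annotations:
        row = {
            "sample_id": a.sample_id, "tissue": a.tissue, "pair_id": a.pair_id,
            "rr_label": a.rr_label, "sf2": a.sf2, "auc": a.auc,
            "timepoint": a.timepoint, "subtype": a.subtype,
            "hpv_status": a.hpv_status,
        }
        for g in flag_genes:
            row[f"genotype_{g}"] = a.genotype_flags.get(g)
        row.update(a.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False,
                              float_format=_FLOAT_FMT)


def write_survival(records: Iterable[SurvivalRecord], path: PathLike) -> None:
    path = Path(path)
    rows = [
        {"sample_id": r.sample_id, "time": r.time, "event": r.event,
         "age": r.age, "node_stage": r.node_stage, "tumor_stage": r.tumor_stage}
        for r in records
    ]
    pd.DataFrame(rows, columns=SURVIVAL_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# Score tables


def read_scores(path: PathLike) -> ScoreTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("sample_id", "score"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{path}: duplicate sample ids {dups[:5]}")
    return ScoreTable(pd.Series(df["score"].to_numpy(float), index=df["sample_id"].astype(str)))


def write_scores(scores: ScoreTable, path: PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame({"sample_id": scores.sample_ids, "score": scores.scores.to_numpy()})
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)
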