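"""Single-sample gene-set enrichment scoring.

The enrichment score (ES) of a gene set in one sample is the sum, over all
genes walked in decreasing expression order, of the difference between the
rank-weighted in-set empirical distribution and the unweighted out-of-set
empirical distribution:

    ES = sum_i [ cum_in(i) / W  -  cum_out(i) / (N - m) ]

where in-set genes contribute weight rank**alpha (rank N = highest
expression, midranks for ties), W is the total in-set weight and m the
in-set size.  The score depends on within-sample ranks only, which makes it
invariant under strictly monotone per-sample transforms and therefore
robust across platforms.

A directional signature is scored as ES(up) - ES(dn); the combined mode
scores the union as a single set.  ``ssgsea_es`` is the straightforward
reference implementation; the matrix scorers share one sort per sample
across gene sets but compute the identical quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix, GeneSetCollection, ScoreTable, SignatureGeneSet
from .errors import ValidationError

MODES = ("directional", "combined")


@dataclass
class SsgseaParams:
    alpha: float = 0.75
    normalize: bool = False
    mode: str = "directional"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")


def rank_genes(sample_values: pd.Series) -> pd.Series:
    """Ranks 1..N with the largest expression receiving rank N.

    Ties get the average rank.  Missing values are excluded; the caller is
    expected to have dropped them.
    """
    vals = sample_values.dropna()
    if vals.size < 2:
        raise ValidationError("need at least 2 genes with values to rank")
    return pd.Series(sps.rankdata(vals.to_numpy()), index=vals.index)


def _traversal(vals: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Walk order (decreasing value, gene symbol on ties) and ordered ranks."""
    genes = vals.index.to_numpy(dtype=object)
    order = np.lexsort((genes, -vals.to_numpy()))
    ranks = sps.rankdata(vals.to_numpy())
    return order, ranks[order]


def _es_from_order(in_mask: np.ndarray, ordered_ranks: np.ndarray,
                   alpha: float) -> float:
    n = in_mask.size
    m = int(in_mask.sum())
    weights = np.where(in_mask, ordered_ranks**alpha, 0.0)
    cum_in = np.cumsum(weights) / weights.sum()
    cum_out = np.cumsum(~in_mask) / (n - m)
    return float(np.sum(cum_in - cum_out))


def ssgsea_es(sample_values: pd.Series, gene_set: Iterable[str],
              params: SsgseaParams | None = None) -> float:
    """Enrichment score of one gene set in one sample."""
    params = params or SsgseaParams()
    vals = sample_values.dropna()
    if vals.size < 2:
        raise ValidationError("need at least 2 measured genes")
    gene_set = set(gene_set)
    present = gene_set & set(vals.index)
    if not present:
        missing = sorted(gene_set)[:10]
        raise ValidationError(f"no gene-set member found in sample; set includes {missing}")
    if len(present) == vals.size:
        raise ValidationError("gene set covers all measured genes (empty complement)")
    order, ordered_ranks = _traversal(vals)
    genes = vals.index.to_numpy(dtype=object)[order]
    in_mask = np.fromiter((g in present for g in genes), dtype=bool, count=genes.size)
    return _es_from_order(in_mask, ordered_ranks, params.alpha)


def _normalize(scores: pd.Series) -> pd.Series:
    rng = scores.max() - scores.min()
    return scores / rng if rng > 0 else scores


def _score_sets(expr: ExpressionMatrix, sets: dict[str, set[str]],
                alpha: float) -> pd.DataFrame:
    """ES for several gene sets over all samples, one sort per sample."""
    index = expr.values.index
    members = {name: index.isin(genes) for name, genes in sets.items()}
    out = {name: {} for name in sets}
    for sid in expr.sample_ids:
        col = expr.sample(sid)
        if col.isna().any():
            vals = col.dropna()
            for name, genes in sets.items():
                present = genes & set(vals.index)
                if not present or len(present) == vals.size:
                    raise ValidationError(
                        f"gene set {name!r} degenerate in sample {sid} after "
                        f"dropping missing values")
                out[name][sid] = ssgsea_es(vals, present, SsgseaParams(alpha=alpha))
            continue
        order, ordered_ranks = _traversal(col)
        for name in sets:
            out[name][sid] = _es_from_order(members[name][order], ordered_ranks, alpha)
    return pd.DataFrame.from_dict(out, orient="index")[expr.sample_ids]


def score_signature(expr: ExpressionMatrix, sig: SignatureGeneSet,
                    params: SsgseaParams | None = None) -> ScoreTable:
    """Per-sample signature score.

    Directional mode: ES(up) - ES(dn); combined mode: ES(up | dn).
    Errors when fewer than half of the signature genes are measured.
    """
    params = params or SsgseaParams()
    measured = set(expr.gene_ids)
    overlap = sig.all_genes & measured
    missing = sorted(sig.all_genes - measured)
    if len(overlap) < 0.5 * len(sig.all_genes):
        raise ValidationError(
            f"only {len(overlap)}/{len(sig.all_genes)} signature genes measured; "
            f"missing: {missing}"
        )
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}", stacklevel=2)
    up = sig.up_genes & measured
    dn = sig.dn_genes & measured
    if params.mode == "combined":
        es = _score_sets(expr, {"all": up | dn}, params.alpha)
        scores = es.loc["all"]
    else:
        sets = {}
        if up:
            sets["up"] = up
        if dn:
            sets["dn"] = dn
        es = _score_sets(expr, sets, params.alpha)
        scores = pd.Series(0.0, index=es.columns)
        if "up" in es.index:
            scores = scores + es.loc["up"]
        if "dn" in es.index:
            scores = scores - es.loc["dn"]
    if params.normalize:
        scores = _normalize(scores)
    return ScoreTable(scores)


def score_collection(expr: ExpressionMatrix, sets: GeneSetCollection,
                     params: SsgseaParams | None = None) -> pd.DataFrame:
    """ES matrix (set x sample); sets without measured genes are skipped."""
    params = params or SsgseaParams()
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    measured = set(expr.gene_ids)
    usable: dict[str, set[str]] = {}
    for name, genes in sets.items():
        present = set(genes) & measured
        if not present or len(present) == len(measured):
            warnings.warn(f"gene set {name!r} skipped (overlap {len(present)})",
                          stacklevel=2)
            continue
        usable[name] = present
    out = _score_sets(expr, usable, params.alpha)
    if params.normalize:
        out = out.apply(_normalize, axis=1)
    return out
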