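"""Single-sample running-sum enrichment scoring of gene sets.

For one sample, genes are rank-normalized and rank-ordered; the enrichment
score ES(S) of a gene set S against the ranked universe L measures whether S
concentrates at the top (ES > 0) or bottom (ES < 0) of the ranking.  Walking
down L, the running sum rises by a (possibly rank-weighted) increment at
every gene in S and falls by 1/(G - |S|) at every other gene; ES is the mean
of the running sum over all G positions, i.e. the integrated hit/miss ECDF
difference normalized by the size of the universe.

With ``alpha = 0`` (the default) every hit contributes equally and the
running sum is exactly ECDF_S - ECDF_notS; ``alpha = 0.25`` weights hits by
their rank-normalized value, the convention of common ssGSEA
implementations.  ES is invariant under any strictly monotone transform of
the expression values because only ranks enter the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signature_builder import GeneSignature

__all__ = ["RankedSample", "rank_normalize", "enrichment_score", "score_matrix"]


@dataclass(frozen=True)
class RankedSample:
    """One sample's gene universe in rank order (highest expression first)."""

    genes: np.ndarray  # ordered gene names, best rank first
    values: np.ndarray  # rank-normalized values, non-increasing, in (0, 1]

    def __len__(self) -> int:
        return len(self.genes)


def rank_normalize(expr_column: pd.Series) -> RankedSample:
    """Rank-normalize one expression column.

    Genes are ranked descending by expression (ties get their average rank);
    the rank-normalized value of a gene with rank r among G genes is
    (G - r + 1)/G, so the top gene maps to 1 and the bottom to 1/G.  The
    returned universe is sorted best-first, with exact ties ordered by gene
    name for determinism.
    """
    values = np.asarray(expr_column, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 genes")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    genes = np.asarray(expr_column.index, dtype=object)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene identifiers")
    ranks = rankdata(-values, method="average")
    norm = (len(values) - ranks + 1.0) / len(values)
    order = np.lexsort((genes, ranks))
    return RankedSample(genes=genes[order], values=norm[order])


def _es_walk(values: np.ndarray, hits: np.ndarray, alpha: float) -> float:
    """Integrated running sum over the ranked universe, divided by G."""
    n = values.size
    n_hits = int(hits.sum())
    if alpha == 0.0:
        weights = hits.astype(float)
    else:
        weights = np.where(hits, values, 0.0) ** alpha * hits
    weights = weights / weights.sum()
    if n_hits == n:
        steps = weights
    else:
        steps = weights - (~hits) / (n - n_hits)
    return float(np.cumsum(steps).sum() / n)


def enrichment_score(
    ranked: RankedSample, signature: GeneSignature, alpha: float = 0.0
) -> float:
    """ES of ``signature`` in one ranked sample.

    Signature genes absent from the universe are dropped with a warning; a
    signature with no overlap at all raises ``ValueError``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    hits = np.isin(ranked.genes, np.asarray(signature.genes, dtype=object))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError(
            f"signature {signature.name!r} shares no genes with the expression universe"
        )
    if n_hits < len(signature.genes):
        warnings.warn(
            f"signature {signature.name!r}: {len(signature.genes) - n_hits} gene(s) "
            "absent from the expression matrix were dropped",
            stacklevel=2,
        )
    return _es_walk(ranked.values, hits, alpha)


def score_matrix(
    expr: pd.DataFrame,
    signatures: Sequence[GeneSignature],
    alpha: float = 0.0,
    *,
    rescale: bool = False,
    protein_coding: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score every sample (column of ``expr``) against every signature.

    Returns a samples x signatures DataFrame of enrichment scores.  The gene
    universe is all rows of ``expr``, optionally restricted to
    ``protein_coding`` identifiers first.  With ``rescale=True`` each
    signature's scores are min-max rescaled to [0, 1] across samples.
    """
    if protein_coding is not None:
        keep = expr.index.intersection(pd.Index(protein_coding))
        if keep.empty:
            raise ValueError("protein-coding filter removed every gene")
        expr = expr.loc[keep]
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError("duplicate signature names")
    out = pd.DataFrame(index=expr.columns, columns=names, dtype=float)
    out.index.name = "sample_id"
    for sample in expr.columns:
        ranked = rank_normalize(expr[sample])
        for sig in signatures:
            try:
                out.at[sample, sig.name] = enrichment_score(ranked, sig, alpha)
            except ValueError as exc:
                raise ValueError(f"sample {sample!r}: {exc}") from exc
    if rescale:
        rng = out.max() - out.min()
        out = (out - out.min()) / rng.replace(0.0, np.nan)
    return out
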