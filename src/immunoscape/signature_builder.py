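"""Construction of minimal immune-cell gene signatures from pure-cell expression data.

A signature ("minimal gene expression signature profile", MGESP) is a short,
cell-type-specific marker list selected from profiles of purified immune
cells.  Candidate markers are prioritised by two statistics:

* **Average rank score (ARS)** — the mean within-sample rank percentile of a
  gene across samples of its cognate cell type.  A gene that is always among
  the most highly expressed genes of, say, purified CD8+ T cells has an ARS
  close to 1 for CD8.
* **Marker evaluation score (MES)** — a specificity contrast: the gene's mean
  expression in the cognate cell type minus its best (maximum) mean over all
  other cell types, divided by the pooled within-type standard deviation.
  Genes whose expression is shared with another lineage score low.

Survivors of the ARS/MES filters are additionally required to be expressed at
a minimum median level in an (optionally separate, e.g. RNA-seq) pure-cell
data set, capped per cell type, and made globally disjoint by assigning each
gene to the cell type where it is most specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSignature",
    "SignatureBuildError",
    "DegenerateInputError",
    "average_rank_score",
    "marker_evaluation_score",
    "rank_stats_table",
    "build_signatures",
]


class SignatureBuildError(ValueError):
    """A cell type ended up with no surviving signature genes."""


class DegenerateInputError(ValueError):
    """Input has zero pooled variance but unequal group means."""


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set: an immune cell type (or any set label) and its members."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def _check_labels(expr: pd.DataFrame, labels: pd.Series) -> pd.Series:
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"samples without cell-type label: {missing}")
    return labels


def _rank_percentiles(expr: pd.DataFrame) -> pd.DataFrame:
    """Within-sample rank percentile of every gene (1 = top expressed, 0 = bottom).

    Ties share their average rank, so the percentile is invariant under any
    strictly monotone transform of the expression values.
    """
    n_genes = expr.shape[0]
    if n_genes < 2:
        raise ValueError("need at least 2 genes to rank")
    ranks = expr.rank(axis=0, ascending=False, method="average")
    return 1.0 - (ranks - 1.0) / (n_genes - 1.0)


def average_rank_score(
    expr: pd.DataFrame, labels: pd.Series, gene: str, cell_type: str
) -> float:
    """ARS of ``gene`` for ``cell_type``: mean rank percentile over cognate samples."""
    if gene not in expr.index:
        raise KeyError(f"unknown gene {gene!r}")
    labels = _check_labels(expr, labels)
    cognate = labels.index[labels == cell_type]
    if len(cognate) == 0:
        raise KeyError(f"no samples labelled {cell_type!r}")
    pct = _rank_percentiles(expr[cognate])
    return float(pct.loc[gene].mean())


def _pooled_sd(expr: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Pooled within-type SD per gene: sqrt(sum (n_i-1) s_i^2 / (N - k))."""
    counts = labels.value_counts()
    n_total = int(counts.sum())
    k = len(counts)
    var = expr.T.groupby(labels).var(ddof=1)  # types x genes; NaN for n_i = 1
    weights = (counts - 1).clip(lower=0)
    ss = var.mul(weights, axis=0).sum(axis=0, skipna=True)
    dof = n_total - k
    if dof <= 0:
        raise ValueError("need at least one cell type with >= 2 samples")
    return np.sqrt(ss / dof)


def marker_evaluation_score(
    expr: pd.DataFrame, labels: pd.Series, gene: str, cell_type: str
) -> float:
    """MES: (cognate mean - best non-cognate mean) / pooled within-type SD."""
    if gene not in expr.index:
        raise KeyError(f"unknown gene {gene!r}")
    labels = _check_labels(expr, labels)
    types = labels.unique()
    if cell_type not in types:
        raise KeyError(f"no samples labelled {cell_type!r}")
    if len(types) < 2:
        raise ValueError("MES requires at least 2 cell types")
    means = expr.loc[gene].groupby(labels).mean()
    spread = float(means[cell_type] - means.drop(cell_type).max())
    sd = float(_pooled_sd(expr.loc[[gene]], labels).iloc[0])
    if sd == 0.0:
        if spread == 0.0:
            return 0.0
        raise DegenerateInputError(
            f"gene {gene!r}: zero pooled SD with unequal type means"
        )
    return spread / sd


def rank_stats_table(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised (genes x cell types) tables of ARS and MES.

    Genes with zero pooled SD get MES 0 when all type means are equal and
    signed infinity otherwise (the noise-free limit of the contrast).
    """
    labels = _check_labels(expr, labels)
    pct = _rank_percentiles(expr)
    ars = pct.T.groupby(labels).mean().T  # genes x types

    means = expr.T.groupby(labels).mean().T  # genes x types
    sd = _pooled_sd(expr, labels)
    types = means.columns
    spread = pd.DataFrame(index=expr.index, columns=types, dtype=float)
    for t in types:
        spread[t] = means[t] - means.drop(columns=t).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mes = spread.div(sd, axis=0)
    zero_sd = sd == 0.0
    if zero_sd.any():
        sub = np.sign(spread.loc[zero_sd]) * np.inf
        mes.loc[zero_sd] = sub.where(spread.loc[zero_sd] != 0.0, 0.0)
    return ars, mes


def build_signatures(
    pure_rnaseq: pd.DataFrame,
    labels: pd.Series,
    *,
    pure_microarray: pd.DataFrame | None = None,
    microarray_labels: pd.Series | None = None,
    ars_min: float = 0.9,
    mes_min: float = 1.0,
    expr_min: float = 1.0,
    max_genes_per_type: int = 25,
    allow: Iterable[str] | None = None,
    deny: Iterable[str] | None = None,
) -> list[GeneSignature]:
    """Select per-cell-type marker signatures from pure-cell expression data.

    Ranking statistics (ARS, MES) are computed on ``pure_microarray`` when a
    second platform is supplied (with its own ``microarray_labels``),
    otherwise on ``pure_rnaseq``; the median-expression floor ``expr_min`` is
    always checked on ``pure_rnaseq`` so that markers are expressed across
    platforms.  ``allow``/``deny`` implement manual curation as gene lists.

    Per cell type, genes passing ARS >= ars_min, MES >= mes_min and median
    cognate expression >= expr_min are ranked by MES and capped at
    ``max_genes_per_type``; a gene selected for several types is kept only
    where its MES is largest, so the emitted signatures are pairwise disjoint.

    Raises :class:`SignatureBuildError` naming every cell type left empty.
    """
    for name, value in [("ars_min", ars_min), ("mes_min", mes_min), ("expr_min", expr_min)]:
        if not np.isfinite(value):
            raise ValueError(f"{name} must be finite")
    if max_genes_per_type < 1:
        raise ValueError("max_genes_per_type must be >= 1")

    labels = _check_labels(pure_rnaseq, labels)
    if pure_microarray is not None:
        if microarray_labels is None:
            raise ValueError("microarray data requires microarray_labels")
        rank_expr = pure_microarray
        rank_labels = _check_labels(pure_microarray, microarray_labels)
        genes = rank_expr.index.intersection(pure_rnaseq.index)
        rank_expr = rank_expr.loc[genes]
    else:
        rank_expr, rank_labels = pure_rnaseq, labels

    types = sorted(rank_labels.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")

    ars, mes = rank_stats_table(rank_expr, rank_labels)
    median_expr = pure_rnaseq.T.groupby(labels).median().T

    allow_set = set(allow) if allow is not None else None
    deny_set = set(deny) if deny is not None else set()

    selected: dict[str, pd.Series] = {}  # type -> MES of capped survivors
    for t in types:
        ok = (ars[t] >= ars_min) & (mes[t] >= mes_min)
        med = median_expr[t].reindex(ars.index)
        ok &= med >= expr_min
        genes_t = ars.index[ok.fillna(False)]
        genes_t = [g for g in genes_t if g not in deny_set]
        if allow_set is not None:
            genes_t = [g for g in genes_t if g in allow_set]
        ranked = mes.loc[genes_t, t].sort_values(ascending=False, kind="mergesort")
        # deterministic order among exact MES ties: gene name
        ranked = ranked.iloc[
            np.lexsort((np.array(ranked.index, dtype=object), -ranked.to_numpy()))
        ]
        selected[t] = ranked.iloc[:max_genes_per_type]

    # global disjointness: each gene goes to the type where its MES is largest
    owner: dict[str, str] = {}
    for t in types:
        for g in selected[t].index:
            if g not in owner:
                owner[g] = t
            else:
                best = owner[g]
                if (mes.at[g, t], t) > (mes.at[g, best], best):
                    owner[g] = t

    empty: list[str] = []
    signatures: list[GeneSignature] = []
    for t in types:
        final = [g for g in selected[t].index if owner[g] == t]
        if not final:
            empty.append(t)
            continue
        signatures.append(
            GeneSignature(name=t, genes=tuple(final), description="MGESP marker set")
        )
    if empty:
        raise SignatureBuildError(
            "no signature genes survived filtering for cell type(s): "
            + ", ".join(empty)
        )
    return signatures
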