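"""Immune-landscape stratification of scored tumor cohorts.

Operations over a samples x cell-types immune score matrix: global quartile
stratification with per-cancer occupancy, pairwise co-infiltration
correlations, chemoattractant-score correlations, per-stage trends with
one-way ANOVA, and unsupervised hierarchical clustering of samples by their
immune composition.
"""

from __future__ import annotations

import io as _stdio
import itertools
import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f_oneway, pearsonr
from skbio import TreeNode

from .signature_builder import GeneSignature
from .ssgsea_engine import score_matrix

__all__ = [
    "QuartileResult",
    "ClusterResult",
    "parse_stage",
    "quartile_stratify",
    "co_infiltration",
    "chemoattractant_correlation",
    "stage_trend",
    "cluster_samples",
    "compartment_scores",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")

_STAGE_RE = re.compile(r"(?i)\b(?:stage\s*)?(IV|III|II|I|[1-4])[ABC]*\b")
_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


def parse_stage(value: object) -> float:
    """Collapse a pathological stage label to ordinal 1-4.

    Accepts integers/floats 1-4 and strings such as ``"Stage IIIA"`` or
    ``"iv"``; sub-stage letters are dropped.  Unparseable or missing values
    map to NaN.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (int, np.integer, float, np.floating)):
        v = float(value)
        return v if v in (1.0, 2.0, 3.0, 4.0) else np.nan
    m = _STAGE_RE.search(str(value))
    if not m:
        return np.nan
    token = m.group(1).upper()
    return float(_ROMAN[token]) if token in _ROMAN else float(token)


@dataclass(frozen=True)
class QuartileResult:
    """Global quartile assignment for one cell type plus per-cancer occupancy."""

    cell_type: str
    assignments: pd.Series  # sample -> "Q1".."Q4" (Q1 = highest scores)
    occupancy: pd.DataFrame  # long: cancer, cell_type, quartile, n, fraction


def quartile_stratify(
    scores: pd.DataFrame, clinical: pd.DataFrame, cell_type: str
) -> QuartileResult:
    """Split all scored samples into four global quartiles of one cell type's score.

    Samples are sorted descending by score (ties broken by sample ID); the
    four groups differ in size by at most one, with any remainder going to
    the higher-score quartiles.  Occupancy is, per cancer, the fraction of
    that cancer's samples landing in each quartile (rows for one cancer sum
    to 1).
    """
    if cell_type not in scores.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    cancers = clinical["cancer_type"].reindex(scores.index)
    if cancers.isna().any():
        missing = cancers.index[cancers.isna()].tolist()
        raise ValueError(f"samples without cancer label: {missing}")
    s = scores[cell_type]
    order = sorted(s.index, key=lambda i: (-s[i], i))
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    labels: dict[str, str] = {}
    pos = 0
    for q, size in zip(QUARTILES, sizes):
        for sample in order[pos : pos + size]:
            labels[sample] = q
        pos += size
    assignments = pd.Series(labels, name="quartile").reindex(scores.index)

    rows = []
    for cancer, group in assignments.groupby(cancers):
        counts = group.value_counts().reindex(QUARTILES, fill_value=0)
        for q in QUARTILES:
            rows.append(
                {
                    "cancer": cancer,
                    "cell_type": cell_type,
                    "quartile": q,
                    "n": int(counts[q]),
                    "fraction": counts[q] / len(group),
                }
            )
    occupancy = pd.DataFrame(rows)
    return QuartileResult(cell_type=cell_type, assignments=assignments, occupancy=occupancy)


def _corr_matrices(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols = scores.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        x, y = scores[a].to_numpy(), scores[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"constant score column in pair ({a!r}, {b!r}); correlation undefined",
                stacklevel=3,
            )
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        rv, pv = pearsonr(x, y)
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def co_infiltration(
    scores: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    per_cancer: bool = False,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Pairwise Pearson correlations between cell-type scores, with p-values.

    Returns ``{stratum: (r_matrix, p_matrix)}``; the stratum is each cancer
    when ``per_cancer`` else the single key ``"all"``.  Strata with fewer
    than 3 samples are skipped with a warning.
    """
    if per_cancer:
        if clinical is None:
            raise ValueError("per_cancer requires a clinical table")
        cancers = clinical["cancer_type"].reindex(scores.index)
        strata = {c: scores.loc[idx] for c, idx in scores.index.groupby(cancers).items()}
    else:
        strata = {"all": scores}
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for name, sub in strata.items():
        if len(sub) < 3:
            warnings.warn(f"stratum {name!r} has < 3 samples; skipped", stacklevel=2)
            continue
        out[name] = _corr_matrices(sub)
    return out


def chemoattractant_correlation(
    expr: pd.DataFrame,
    chemo_sets: Sequence[GeneSignature],
    scores: pd.DataFrame,
    alpha: float = 0.0,
) -> pd.DataFrame:
    """Correlate chemoattractant gene-set enrichment with infiltration scores.

    Chemoattractant sets are scored with the same running-sum engine on the
    same samples, then each (chemo set, cell type) pair gets a Pearson r and
    p-value.  Returns a long DataFrame.
    """
    chemo_scores = score_matrix(expr, chemo_sets, alpha)
    common = chemo_scores.index.intersection(scores.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    chemo_scores, scores = chemo_scores.loc[common], scores.loc[common]
    rows = []
    for chemo in chemo_scores.columns:
        for ct in scores.columns:
            x, y = chemo_scores[chemo].to_numpy(), scores[ct].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"chemo_set": chemo, "cell_type": ct, "r": np.nan, "p": np.nan})
                continue
            r, p = pearsonr(x, y)
            rows.append({"chemo_set": chemo, "cell_type": ct, "r": r, "p": p})
    return pd.DataFrame(rows)


def stage_trend(
    scores: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Median score per stage and one-way ANOVA across stages, per (cancer, cell type).

    Stage labels are parsed to ordinal 1-4 (:func:`parse_stage`); stages with
    fewer than 2 samples are excluded from the ANOVA, and cancers with fewer
    than 2 usable stages are skipped with a warning.
    """
    cancers = clinical["cancer_type"].reindex(scores.index)
    stages = clinical["stage"].reindex(scores.index).map(parse_stage)
    rows = []
    for cancer, idx in scores.index.groupby(cancers).items():
        st = stages.loc[idx].dropna()
        usable = [v for v, grp in st.groupby(st) if len(grp) >= 2]
        if len(usable) < 2:
            warnings.warn(
                f"cancer {cancer!r}: fewer than 2 stages with >= 2 samples; skipped",
                stacklevel=2,
            )
            continue
        for ct in scores.columns:
            groups = [
                scores.loc[st.index[st == v], ct].to_numpy() for v in usable
            ]
            pval = f_oneway(*groups).pvalue
            medians = {
                f"median_stage{int(v)}": float(
                    scores.loc[st.index[st == v], ct].median()
                )
                for v in (1, 2, 3, 4)
                if (st == v).any()
            }
            rows.append(
                {
                    "cancer": cancer,
                    "cell_type": ct,
                    **medians,
                    "anova_p": float(pval),
                    "significant": bool(pval < alpha),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterResult:
    """Hierarchical clustering of samples on their immune score profile."""

    labels: pd.Series  # sample -> cluster id 1..k
    linkage_matrix: np.ndarray
    newick: str


def cluster_samples(scores: pd.DataFrame, k: int = 4) -> ClusterResult:
    """Agglomerative clustering (Euclidean distance, complete linkage), cut at k.

    Cluster ids are relabelled deterministically by the lexicographically
    smallest member sample, so the partition does not depend on input row
    order (up to label names).
    """
    n = len(scores)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    ordered = scores.sort_index(kind="mergesort")
    z = linkage(ordered.to_numpy(dtype=float), method="complete", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=ordered.index, name="cluster")
    remap: dict[int, int] = {}
    for sample in labels.index:  # already sorted lexicographically
        c = labels[sample]
        if c not in remap:
            remap[c] = len(remap) + 1
    labels = labels.map(remap)
    tree = TreeNode.from_linkage_matrix(z, list(ordered.index))
    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    return ClusterResult(
        labels=labels.reindex(scores.index),
        linkage_matrix=z,
        newick=buf.getvalue().strip(),
    )


def compartment_scores(
    expr: pd.DataFrame,
    compartment_sets: Sequence[GeneSignature],
    alpha: float = 0.0,
) -> pd.DataFrame:
    """Stromal/immune/epithelial (or any user-supplied compartment) enrichment.

    Pure delegation to :func:`immunoscape.ssgsea_engine.score_matrix` with
    gene sets such as the stromal/immune signatures of Yoshihara et al.
    """
    return score_matrix(expr, compartment_sets, alpha)
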