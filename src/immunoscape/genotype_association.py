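"""Mutation-infiltration association: are carriers of a mutation more (or less)
infiltrated by a given immune cell type?

Per cancer, per mutated gene (or gene + protein change), per cell type, the
immune scores of carriers and non-carriers are compared with a Welch
two-sample t-test.  Raw p-values are filtered at a configurable alpha
(default 0.005); a Benjamini-Hochberg adjusted column is reported alongside
for honest reuse, but is not used for the filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = ["AssociationResults", "associate"]

RESULT_COLUMNS = [
    "cancer",
    "gene",
    "protein_change",
    "cell_type",
    "n_carriers",
    "n_noncarriers",
    "mean_diff",
    "t_stat",
    "p_value",
    "p_adjusted",
    "direction",
]


@dataclass(frozen=True)
class AssociationResults:
    """Associations passing the filter plus degenerate comparisons that could not be tested."""

    table: pd.DataFrame  # RESULT_COLUMNS, sorted by p_value
    degenerate: pd.DataFrame  # cancer, gene, protein_change, reason


def associate(
    scores: pd.DataFrame,
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    *,
    min_carriers: int = 5,
    alpha: float = 0.005,
    variant_level: bool = False,
) -> AssociationResults:
    """Test every (cancer, mutation, cell type) combination for a score shift.

    ``mutations`` is MAF-like (``Tumor_Sample_Barcode``, ``Hugo_Symbol``,
    optionally ``Protein_Change``); repeated (sample, gene) rows collapse to
    one carrier flag.  ``variant_level=True`` groups by gene + protein change
    instead of gene alone.  Mutations whose carrier group within a cancer is
    smaller than ``min_carriers``, or that leave no comparison group, are
    reported as degenerate rather than tested.  Direction is "enriched" when
    carriers score higher on average.
    """
    if min_carriers < 2:
        raise ValueError("min_carriers must be >= 2")
    cancers = clinical["cancer_type"].reindex(scores.index)
    if cancers.isna().any():
        raise ValueError("every scored sample needs a cancer label")

    muts = mutations.copy()
    if variant_level:
        if "Protein_Change" not in muts.columns:
            raise ValueError("variant_level requires a Protein_Change column")
        muts["_key"] = list(zip(muts["Hugo_Symbol"], muts["Protein_Change"]))
    else:
        muts["_key"] = [(g, "") for g in muts["Hugo_Symbol"]]

    carrier_sets: dict[tuple[str, str], set] = {}
    for key, grp in muts.groupby("_key"):
        carrier_sets[key] = set(grp["Tumor_Sample_Barcode"])

    rows: list[dict] = []
    degenerate: list[dict] = []
    for cancer, idx in scores.index.groupby(cancers).items():
        idx = pd.Index(idx)
        any_carrier = any(carrier_sets[k] & set(idx) for k in carrier_sets)
        if carrier_sets and not any_carrier:
            warnings.warn(f"cancer {cancer!r}: no carriers for any gene; skipped", stacklevel=2)
            continue
        for (gene, change), samples in sorted(carrier_sets.items()):
            carriers = idx.intersection(pd.Index(sorted(samples)))
            noncarriers = idx.difference(carriers)
            if len(carriers) < min_carriers:
                continue
            if len(noncarriers) < 2:
                degenerate.append(
                    {
                        "cancer": cancer,
                        "gene": gene,
                        "protein_change": change,
                        "reason": "no comparison group",
                    }
                )
                continue
            for ct in scores.columns:
                x = scores.loc[carriers, ct].to_numpy(dtype=float)
                y = scores.loc[noncarriers, ct].to_numpy(dtype=float)
                t, p = ttest_ind(x, y, equal_var=False)
                diff = float(x.mean() - y.mean())
                rows.append(
                    {
                        "cancer": cancer,
                        "gene": gene,
                        "protein_change": change,
                        "cell_type": ct,
                        "n_carriers": len(carriers),
                        "n_noncarriers": len(noncarriers),
                        "mean_diff": diff,
                        "t_stat": float(t),
                        "p_value": float(p),
                        "direction": "enriched" if diff > 0 else "depleted",
                    }
                )

    table = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "p_adjusted"])
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table[RESULT_COLUMNS]
        table = table[table["p_value"] <= alpha].sort_values(
            ["p_value", "cancer", "gene", "cell_type"], kind="mergesort"
        )
        table = table.reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=RESULT_COLUMNS)
    return AssociationResults(
        table=table,
        degenerate=pd.DataFrame(
            degenerate, columns=["cancer", "gene", "protein_change", "reason"]
        ),
    )
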