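"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import immunoscape as im
from immunoscape import signature_builder as sb
from immunoscape import ssgsea_engine as se


@pytest.fixture(scope="session")
def pure_cells():
    """Full 8-type pure-cell compendium (20 samples/type), fixed seed."""
    return im.simulate_pure_cells(im.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def planted_signatures(pure_cells):
    """GeneSignature objects built from the planted marker map (ground truth)."""
    return [
        sb.GeneSignature(ct, genes, "planted markers")
        for ct, genes in pure_cells.markers.items()
    ]


@pytest.fixture(scope="session")
def pure_scores(pure_cells, planted_signatures):
    """Score matrix of the pure-cell samples against the planted signatures."""
    return se.score_matrix(pure_cells.expression, planted_signatures)


@pytest.fixture(scope="session")
def tiny_pure():
    """2 cell types, 5 markers each, 10 background genes, 3 samples/type."""
    cfg = im.SimulationConfig(
        cell_types=("A", "B"),
        n_markers_per_type=5,
        n_background_genes=10,
        n_samples_per_type=3,
        seed=1,
    )
    return im.simulate_pure_cells(cfg)


def es_oracle(values: np.ndarray, hits: np.ndarray, alpha: float) -> float:
    """Independent integrated-ECDF enrichment score, coded as a plain loop.

    At every position of the ranked universe, the weighted ECDF of the hit
    set minus the ECDF of the misses is accumulated; the integral is divided
    by the universe size.  Used as the oracle against the production
    running-sum implementation.
    """
    g = len(values)
    n_hit = int(hits.sum())
    denom_hit = sum(values[j] ** alpha for j in range(g) if hits[j])
    total = 0.0
    p_hit = 0.0
    p_miss = 0.0
    for i in range(g):
        if hits[i]:
            p_hit += values[i] ** alpha / denom_hit
        else:
            p_miss += 1.0 / (g - n_hit)
        total += p_hit - p_miss
    return total / g
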