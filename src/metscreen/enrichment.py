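"""Over-representation analysis of a selected gene list against gene sets.

One-sided hypergeometric test: given a universe of U genes, a selected list
of n of them and a gene set containing K universe genes, the p-value is
P(X >= k) for X ~ Hypergeometric(U, K, n), where k is the observed overlap.
Benjamini-Hochberg step-up adjustment controls the FDR across sets.

The universe should be the genes that could have been selected (e.g. all
genes passing the expression floor), not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import GeneSetCollection, ValidationError


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    universe_size: int
    selected_size: int
    set_size: int
    overlap: int
    p_value: float
    q_value: float | None = None


def hypergeom_overrep(
    selected: Sequence[str],
    set_members: Sequence[str],
    universe: Sequence[str],
    set_name: str = "set",
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test for one gene set.

    ``selected`` must be a subset of ``universe``; ``set_members`` is
    intersected with the universe before testing.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty universe")
    selected_set = set(selected)
    outside = selected_set - universe_set
    if outside:
        raise ValidationError(
            f"selected genes outside the universe: {sorted(outside)[:5]}"
        )
    members = set(set_members) & universe_set
    overlap = len(selected_set & members)
    u, k_set, n_sel = len(universe_set), len(members), len(selected_set)
    p = float(hypergeom.sf(overlap - 1, u, k_set, n_sel))
    return EnrichmentResult(
        set_name=set_name,
        universe_size=u,
        selected_size=n_sel,
        set_size=k_set,
        overlap=overlap,
        p_value=min(p, 1.0),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_collection(
    selected: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Test every set in a collection and BH-adjust across sets.

    Returns one row per set, in collection order, with columns matching
    :class:`EnrichmentResult`.
    """
    results = [
        hypergeom_overrep(selected, collection[name], universe, set_name=name)
        for name in collection.names
    ]
    qs = bh_adjust([r.p_value for r in results])
    results = [replace(r, q_value=float(q)) for r, q in zip(results, qs)]
    return pd.DataFrame([r.__dict__ for r in results])
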