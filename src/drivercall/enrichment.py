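"""Hypergeometric pathway enrichment of driver genes.

Each gene set is tested for over-representation of the final driver
genes against a background universe (by default all genes observed in
the cohort): with N background genes, K of them in the set, n driver
genes and k drivers inside the set, the p-value is the upper
hypergeometric tail

    p = sum_{i >= k} C(K, i) C(N - K, n - i) / C(N, n),

BH-corrected across all tested sets.  Sets are intersected with the
background before testing; flat sets only (no GO-graph propagation).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .genes import bh_correct
from .io import GeneSetCollection, normalize_symbol

__all__ = ["hypergeom_enrich"]

RESULT_COLUMNS = [
    "set_id", "set_name", "k", "K", "n", "N",
    "p_value", "q_value", "significant", "overlap_genes",
]


def hypergeom_enrich(
    driver_genes: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    fdr_threshold: float = 0.05,
    min_set_size: int = 3,
    max_set_size: int = 5000,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH FDR control.

    Sets smaller than ``min_set_size`` or larger than ``max_set_size``
    after intersection with the background are skipped.  Results are
    sorted by q-value then p-value; ``significant`` marks
    q <= ``fdr_threshold``.
    """
    bg = {normalize_symbol(g) for g in background}
    if not bg:
        raise ValueError("background universe is empty")
    drivers = {normalize_symbol(g) for g in driver_genes}
    if not drivers:
        raise ValueError("driver gene set is empty")
    drivers &= bg
    if not drivers:
        raise ValueError("no driver gene is present in the background universe")

    N = len(bg)
    n = len(drivers)
    rows = []
    for set_id, (set_name, members) in collection.sets.items():
        in_bg = members & bg
        K = len(in_bg)
        if K == 0 or K < min_set_size or K > max_set_size:
            continue
        overlap = sorted(in_bg & drivers)
        k = len(overlap)
        # survival function at k-1 gives P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_id": set_id, "set_name": set_name, "k": k, "K": K,
             "n": n, "N": N, "p_value": min(p, 1.0),
             "overlap_genes": ";".join(overlap)}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df["q_value"] = bh_correct(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] <= fdr_threshold
    df = df.sort_values(["q_value", "p_value", "set_id"], kind="mergesort")
    return df[RESULT_COLUMNS].reset_index(drop=True)
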