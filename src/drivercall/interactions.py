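"""Pairwise mutual exclusivity / co-occurrence among top driver genes.

For each unordered pair among the top-k ranked driver genes, samples
are cross-tabulated by non-silent mutation status into a 2x2 table and
tested with the two-sided Fisher exact test (point-probability rule:
the p-value sums hypergeometric probabilities of tables no more likely
than the observed one).  The direction comes from the sample odds
ratio (n11*n00)/(n10*n01): co-occurrence when OR > 1, mutual
exclusivity when OR < 1, with 0 and infinity permitted.  Pairs are
labeled at raw p < 0.05 and p < 0.01; a BH-corrected column is
emitted additionally.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .genes import bh_correct
from .io import MutationRecord, normalize_symbol
from .mutations import NONSILENT_CLASSES

__all__ = ["mutation_matrix", "pairwise_interactions"]

RESULT_COLUMNS = [
    "gene_a", "gene_b", "n11", "n10", "n01", "n00",
    "odds_ratio", "p_value", "q_value", "direction", "label",
]


def mutation_matrix(
    cohort: Iterable[MutationRecord],
    genes: Sequence[str],
    include_silent: bool = False,
) -> pd.DataFrame:
    """Binary sample x gene mutation-status matrix.

    A sample counts as mutated in a gene if it carries any non-silent
    mutation there (``include_silent=True`` counts every class).
    Every sample in the cohort contributes a row, mutated or not.
    """
    norm_genes = [normalize_symbol(g) for g in genes]
    samples = sorted({r.sample_id for r in cohort})
    mat = pd.DataFrame(False, index=samples, columns=norm_genes)
    wanted = set(norm_genes)
    for rec in cohort:
        g = normalize_symbol(rec.gene)
        if g not in wanted:
            continue
        if include_silent or rec.variant_classification in NONSILENT_CLASSES:
            mat.loc[rec.sample_id, g] = True
    mat.columns = list(genes)
    return mat


def pairwise_interactions(
    cohort: Iterable[MutationRecord],
    genes: Sequence[str],
    top_k: int = 50,
    include_silent: bool = False,
) -> pd.DataFrame:
    """Fisher-exact co-occurrence/exclusivity over top-ranked genes.

    ``genes`` is a ranked driver-gene list; the first ``top_k`` entries
    are analyzed.  Pairs involving a gene mutated in zero samples are
    reported with p = 1 and direction ``ns``.
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    cohort = list(cohort)
    top = list(dict.fromkeys(genes))[:top_k]
    if len(top) < 2:
        raise ValueError("need at least two genes to form pairs")
    mat = mutation_matrix(cohort, top, include_silent=include_silent)
    n_samples = mat.shape[0]

    rows = []
    for a, b in combinations(top, 2):
        va = mat[a].to_numpy()
        vb = mat[b].to_numpy()
        n11 = int(np.sum(va & vb))
        n10 = int(np.sum(va & ~vb))
        n01 = int(np.sum(~va & vb))
        n00 = n_samples - n11 - n10 - n01
        if (n11 + n10 == 0) or (n11 + n01 == 0):
            # a gene mutated in zero samples carries no information
            rows.append({"gene_a": a, "gene_b": b, "n11": n11, "n10": n10,
                         "n01": n01, "n00": n00, "odds_ratio": np.nan,
                         "p_value": 1.0, "direction": "ns"})
            continue
        # scipy's statistic is the sample odds ratio (n11*n00)/(n10*n01),
        # with 0, inf and nan for the degenerate cells
        odds, p = fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
        if np.isnan(odds):
            direction = "ns"
        elif odds > 1:
            direction = "co-occurrence"
        elif odds < 1:
            direction = "mutual_exclusivity"
        else:
            direction = "ns"
        rows.append({"gene_a": a, "gene_b": b, "n11": n11, "n10": n10,
                     "n01": n01, "n00": n00, "odds_ratio": float(odds),
                     "p_value": float(p), "direction": direction})
    df = pd.DataFrame(rows)
    df["q_value"] = bh_correct(df["p_value"].to_numpy())
    df["label"] = np.select(
        [df["p_value"] < 0.01, df["p_value"] < 0.05],
        ["p<0.01", "p<0.05"],
        default="ns",
    )
    return df[RESULT_COLUMNS]
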