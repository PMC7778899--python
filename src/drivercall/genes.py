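"""Gene-level prioritization: combined significance, weighted consensus
scoring over driver catalogs, five-tier classification and druggability.

The significance stream combines two per-gene p-values (a coverage-
and-expression-aware recurrence test like MutSigCV, and a nucleotide-
context positional test like MutPanning) with Fisher's method, applies
Benjamini-Hochberg control, and calls genes at FDR <= 0.05.  That set
is injected into a 16-catalog consensus vote (an improved Borda count:
weight 10 per gold-standard catalog, 1 per supplementary catalog), and
the summed score maps onto five pathogenicity levels.  Level-4 genes
(score >= 20) that harbor at least one driver or extreme mutation are
the final driver genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import DriverSetCatalog, SIGNIFICANCE_SET_NAME
from .io import DrugGeneTable, MutationRecord, normalize_symbol
from .mutations import MutationCall, NONSILENT_CLASSES

__all__ = [
    "P_FLOOR",
    "TierAssignment",
    "fisher_combine",
    "bh_correct",
    "combine_gene_pvalues",
    "significant_genes",
    "consensus_score",
    "tier_classify",
    "classify_tiers",
    "finalize_driver_genes",
    "frequency_pvalue_standin",
    "annotate_druggability",
]

#: Floor applied to p-values before taking logs, so that numerically
#: underflowed zeros do not break Fisher's method.
P_FLOOR = 1e-300

LEVEL_LABELS = {
    0: "non-pathogenic",
    1: "possible pathogenic",
    2: "likely pathogenic",
    3: "probable pathogenic",
    4: "pathogenic",
}


@dataclass(frozen=True)
class TierAssignment:
    gene: str
    consensus_score: int
    level: int
    is_driver_gene: bool = False


def fisher_combine(p1: float, p2: float) -> float:
    """Combine two p-values with Fisher's method (chi-square, 4 df).

    X = -2(ln p1 + ln p2) is chi-square distributed with 4 degrees of
    freedom under the joint null; the upper-tail probability has the
    closed form exp(-X/2) * (1 + X/2), which is what this returns.
    """
    for p in (p1, p2):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0, 1], got {p} "
                             f"(floor underflowed values at {P_FLOOR} first)")
    x = -2.0 * (math.log(p1) + math.log(p2))
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def bh_correct(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def combine_gene_pvalues(
    p_mutsig: Mapping[str, float],
    p_mutpanning: Mapping[str, float],
) -> pd.DataFrame:
    """Merge two per-gene p-value streams into a gene statistics table.

    Genes covered by only one method get combined p equal to that
    method's p-value (the missing stream is treated as 1.0) and are
    flagged in the ``single_method`` column.  Combined p-values are BH
    corrected into the ``q_value`` column.
    """
    keys: dict[str, str] = {}
    for src in (p_mutsig, p_mutpanning):
        for g in src:
            keys.setdefault(normalize_symbol(g), g)
    norm_ms = {normalize_symbol(g): p for g, p in p_mutsig.items()}
    norm_mp = {normalize_symbol(g): p for g, p in p_mutpanning.items()}

    rows = []
    for norm in sorted(keys):
        pm = norm_ms.get(norm)
        pp = norm_mp.get(norm)
        single = (pm is None) != (pp is None)
        p1 = max(pm if pm is not None else 1.0, P_FLOOR)
        p2 = max(pp if pp is not None else 1.0, P_FLOOR)
        rows.append(
            {
                "gene": keys[norm],
                "p_mutsig": pm if pm is not None else np.nan,
                "p_mutpanning": pp if pp is not None else np.nan,
                "p_combined": fisher_combine(p1, p2),
                "single_method": single,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["gene", "p_mutsig", "p_mutpanning", "p_combined",
                     "single_method", "q_value"]
        )
    df["q_value"] = bh_correct(df["p_combined"].to_numpy())
    return df


def significant_genes(stats_table: pd.DataFrame, fdr_threshold: float = 0.05) -> set[str]:
    """Genes with BH-corrected combined p <= the FDR threshold.

    This is the significance-derived driver set that is installed in
    the catalog (as a Group1 set) before consensus scoring.
    """
    hit = stats_table.loc[stats_table["q_value"] <= fdr_threshold, "gene"]
    return set(hit.astype(str))


def inject_significance_set(catalog: DriverSetCatalog, genes: Iterable[str]) -> None:
    """Install the combined-significance gene set as a Group1 catalog."""
    catalog.add_set(SIGNIFICANCE_SET_NAME, list(genes), group1=True)


def consensus_score(gene: str, catalog: DriverSetCatalog) -> int:
    """Weighted membership sum of a gene over the driver catalogs.

    Group1 sets contribute 10, Group2 sets contribute 1; a gene covered
    by no catalog scores 0.
    """
    return catalog.score(gene)


def tier_classify(score: int) -> int:
    """Map a consensus score onto the five pathogenicity levels.

    Level 0: score = 0; Level 1: score = 1; Level 2: 1 < score <= 10;
    Level 3: 10 < score < 20; Level 4: score >= 20 (driver-gene tier).
    """
    if score < 0:
        raise ValueError(f"consensus score must be non-negative, got {score}")
    if score == 0:
        return 0
    if score == 1:
        return 1
    if score <= 10:
        return 2
    if score < 20:
        return 3
    return 4


def classify_tiers(genes: Iterable[str], catalog: DriverSetCatalog) -> list[TierAssignment]:
    """Score and tier a collection of genes against a catalog."""
    out = []
    for g in genes:
        s = catalog.score(g)
        out.append(TierAssignment(gene=g, consensus_score=s, level=tier_classify(s)))
    return out


def finalize_driver_genes(
    tiers: Iterable[TierAssignment],
    mutation_calls: Iterable[MutationCall],
) -> set[str]:
    """Final driver genes: Level 4 and >= 1 driver or extreme mutation."""
    flagged = {
        normalize_symbol(c.gene)
        for c in mutation_calls
        if c.is_driver or c.is_extreme
    }
    return {
        t.gene
        for t in tiers
        if t.level == 4 and normalize_symbol(t.gene) in flagged
    }


def frequency_pvalue_standin(
    cohort: Iterable[MutationRecord],
    gene_lengths: Mapping[str, int],
) -> dict[str, float]:
    """Length-adjusted recurrence p-values from a uniform-rate binomial.

    For each gene, the observed non-silent mutation count is tested
    against a binomial upper tail with ``length * n_samples`` per-bp
    opportunities at the cohort-wide per-bp non-silent rate.  This is a
    deliberately simple stand-in used to exercise the significance
    stream on synthetic cohorts; it models no covariates and is NOT a
    replacement for MutSigCV or MutPanning on real data.
    """
    cohort = list(cohort)
    lengths = {normalize_symbol(g): int(l) for g, l in gene_lengths.items()}
    if any(l <= 0 for l in lengths.values()):
        raise ValueError("gene lengths must be positive")
    n_samples = len({r.sample_id for r in cohort})
    if n_samples == 0:
        raise ValueError("cohort has no samples")

    counts: dict[str, int] = {g: 0 for g in lengths}
    display: dict[str, str] = {}
    skipped: set[str] = set()
    for rec in cohort:
        norm = normalize_symbol(rec.gene)
        display.setdefault(norm, rec.gene)
        if norm not in lengths:
            skipped.add(rec.gene)
            continue
        if rec.variant_classification in NONSILENT_CLASSES:
            counts[norm] += 1
    if skipped:
        warnings.warn(
            f"{len(skipped)} mutated gene(s) absent from the length table "
            f"were skipped (e.g. {sorted(skipped)[:3]})",
            stacklevel=2,
        )

    total_bp = sum(lengths.values())
    total_nonsilent = sum(counts.values())
    rate = total_nonsilent / (total_bp * n_samples) if total_nonsilent else 0.0

    pvals: dict[str, float] = {}
    for norm, length in lengths.items():
        name = display.get(norm, norm)
        if rate == 0.0:
            pvals[name] = 1.0
            continue
        trials = length * n_samples
        # upper tail P(X >= c) under Binomial(trials, rate)
        pvals[name] = float(stats.binom.sf(counts[norm] - 1, trials, rate))
    return pvals


@dataclass
class DruggabilityAnnotation:
    """Per-gene drug annotations plus combination-therapy candidates."""

    gene_drugs: pd.DataFrame            # gene, drugs, interaction_types, sources, actionable
    combination_candidates: pd.DataFrame | None = None  # sample_id, n_actionable_genes, combination_candidate


def annotate_druggability(
    genes: Iterable[str],
    drug_table: DrugGeneTable,
    cohort: Iterable[MutationRecord] | None = None,
) -> DruggabilityAnnotation:
    """Left-join driver genes onto a drug-gene interaction table.

    A gene is *actionable* if it has any entry in the table.  When a
    cohort is supplied, each sample mutated (non-silently) in >= 2
    actionable driver genes is flagged as a combination-therapy
    candidate.
    """
    genes = list(genes)
    tab = drug_table.table.copy()
    tab["_norm"] = tab["gene"].map(normalize_symbol)
    grouped = tab.groupby("_norm").agg(
        drugs=("drug", lambda s: ";".join(sorted(set(s)))),
        interaction_types=("interaction_type", lambda s: ";".join(sorted({x for x in s if x}))),
        sources=("source", lambda s: ";".join(sorted({x for x in s if x}))),
    )
    rows = []
    actionable: set[str] = set()
    for g in genes:
        norm = normalize_symbol(g)
        if norm in grouped.index:
            r = grouped.loc[norm]
            rows.append({"gene": g, "drugs": r["drugs"],
                         "interaction_types": r["interaction_types"],
                         "sources": r["sources"], "actionable": True})
            actionable.add(norm)
        else:
            rows.append({"gene": g, "drugs": "", "interaction_types": "",
                         "sources": "", "actionable": False})
    gene_drugs = pd.DataFrame(
        rows, columns=["gene", "drugs", "interaction_types", "sources", "actionable"]
    )

    combos = None
    if cohort is not None:
        per_sample: dict[str, set[str]] = {}
        for rec in cohort:
            per_sample.setdefault(rec.sample_id, set())
            if (rec.variant_classification in NONSILENT_CLASSES
                    and normalize_symbol(rec.gene) in actionable):
                per_sample[rec.sample_id].add(normalize_symbol(rec.gene))
        combos = pd.DataFrame(
            [
                {"sample_id": s, "n_actionable_genes": len(gs),
                 "combination_candidate": len(gs) >= 2}
                for s, gs in sorted(per_sample.items())
            ],
            columns=["sample_id", "n_actionable_genes", "combination_candidate"],
        )
    return DruggabilityAnnotation(gene_drugs=gene_drugs, combination_candidates=combos)
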