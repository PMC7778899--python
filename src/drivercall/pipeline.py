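"""End-to-end orchestration of the driver-prioritization workflow.

Stage order is fixed: hypermutator filter -> mutation-level driver and
extreme calls -> per-gene p-value combination and BH correction ->
injection of the significance-derived set into the driver catalog ->
consensus scores and tiers -> final driver genes -> Gaussian
driverness scores per entity class -> pathway enrichment -> pairwise
interactions among the top drivers -> drug-gene annotation.

One run covers one cohort (one cancer type); a pan-cancer analysis is
a rerun on the pooled MAF.  Outputs are written only after every
requested stage succeeds, so a failing run leaves no partial tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import DriverSetCatalog, DEFAULT_GROUP1_NAMES
from .enrichment import hypergeom_enrich
from .genes import (
    annotate_druggability,
    classify_tiers,
    combine_gene_pvalues,
    finalize_driver_genes,
    frequency_pvalue_standin,
    inject_significance_set,
    significant_genes,
)
from .interactions import pairwise_interactions
from .io import (
    normalize_symbol,
    read_driver_sets,
    read_drug_table,
    read_gene_list,
    read_gmt,
    read_maf,
    read_pvalue_table,
    write_results,
)
from .mutations import (
    NONSILENT_CLASSES,
    call_driver_mutations,
    filter_hypermutated,
)
from .scoring import driverness_scores

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and labels for one cohort run.

    Either both p-value tables are supplied, or ``gene_lengths`` is
    given and the binomial stand-in generates both streams (synthetic
    runs).  ``gmt`` and ``drug_table`` are optional; their stages are
    skipped with a manifest note when absent.
    """

    maf: str | Path = ""
    mutsig_pvals: str | Path | None = None
    mutpanning_pvals: str | Path | None = None
    gene_lengths: str | Path | None = None
    driver_set_dir: str | Path | None = None
    group1: tuple[str, ...] = DEFAULT_GROUP1_NAMES
    gmt: str | Path | None = None
    drug_table: str | Path | None = None
    background: str | Path | None = None
    driver_score_threshold: float = 0.95
    min_recurrence: int = 2
    reve_threshold: float = 0.5
    fdr_threshold: float = 0.05
    top_k: int = 50
    max_mutations_per_sample: int = 1000
    sigma_convention: str = "population"
    cohort_label: str = "cohort"
    out_dir: str | Path = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "group1" in data and isinstance(data["group1"], list):
            data["group1"] = tuple(data["group1"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    mutation_table: pd.DataFrame
    gene_table: pd.DataFrame
    enrichment_table: pd.DataFrame | None
    interaction_table: pd.DataFrame | None
    drug_gene_table: pd.DataFrame | None
    combination_table: pd.DataFrame | None
    driver_genes: set[str]
    manifest: dict = field(default_factory=dict)


def _mutation_table(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "gene": c.gene,
                "variant_classification": c.variant_classification,
                "n_patients": c.n_patients,
                "max_ai_driver": np.nan if c.max_ai_driver is None else c.max_ai_driver,
                "max_reve": np.nan if c.max_reve is None else c.max_reve,
                "reve_percentile": np.nan if c.reve_percentile is None else c.reve_percentile,
                "is_driver": c.is_driver, "is_extreme": c.is_extreme,
            }
            for c in calls
        ]
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage of the workflow for one cohort.

    Returns the result bundle and writes the TSV tables plus a JSON
    manifest (versions, config hash, per-stage counts) to
    ``config.out_dir``.  Identical config and inputs give identical
    outputs.
    """
    manifest: dict = {
        "cohort": config.cohort_label,
        "config_hash": config.config_hash(),
        "versions": {
            "drivercall": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "notes": [],
    }
    counts = manifest["stages"]

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return deco

    @stage("read_maf")
    def records():
        recs = read_maf(config.maf)
        counts["mutations_in"] = len(recs)
        return recs

    @stage("hypermutator_filter")
    def filtered():
        kept, removed = filter_hypermutated(records, config.max_mutations_per_sample)
        counts["hypermutated_samples_removed"] = len(removed)
        counts["mutations_retained"] = len(kept)
        return kept

    @stage("mutation_calls")
    def calls():
        out = call_driver_mutations(
            filtered,
            score_threshold=config.driver_score_threshold,
            min_recurrence=config.min_recurrence,
            reve_threshold=config.reve_threshold,
        )
        counts["distinct_mutations"] = len(out)
        counts["driver_mutations"] = sum(c.is_driver for c in out)
        counts["extreme_mutations"] = sum(c.is_extreme for c in out)
        return out

    @stage("gene_pvalues")
    def stats():
        if config.mutsig_pvals and config.mutpanning_pvals:
            p1 = read_pvalue_table(config.mutsig_pvals)
            p2 = read_pvalue_table(config.mutpanning_pvals)
        elif config.gene_lengths:
            lengths = read_pvalue_table(config.gene_lengths)  # (gene, length)
            standin = frequency_pvalue_standin(
                filtered, {g: int(v) for g, v in lengths.items()}
            )
            manifest["notes"].append(
                "per-gene p-values from the binomial stand-in (both streams)"
            )
            p1 = p2 = standin
        else:
            raise ValueError(
                "supply mutsig_pvals and mutpanning_pvals, or gene_lengths "
                "for the stand-in"
            )
        df = combine_gene_pvalues(p1, p2)
        counts["genes_tested"] = len(df)
        return df

    @stage("catalog")
    def catalog() -> DriverSetCatalog:
        if config.driver_set_dir:
            paths = {
                p.stem: p
                for p in sorted(Path(config.driver_set_dir).glob("*.txt"))
            }
            cat = read_driver_sets(paths, group1_names=list(config.group1))
        else:
            cat = DriverSetCatalog(group1_names=tuple(config.group1))
        sig = significant_genes(stats, config.fdr_threshold)
        inject_significance_set(cat, sig)
        counts["significance_set_size"] = len(sig)
        counts["driver_sets"] = len(cat)
        return cat

    @stage("tiers")
    def tiers():
        maf_genes = sorted({r.gene for r in filtered}, key=normalize_symbol)
        out = classify_tiers(maf_genes, catalog)
        counts["genes_per_level"] = {
            lvl: sum(t.level == lvl for t in out) for lvl in range(5)
        }
        return out

    @stage("finalize_drivers")
    def drivers():
        out = finalize_driver_genes(tiers, calls)
        counts["driver_genes"] = len(out)
        return out

    @stage("gene_table")
    def gene_table():
        per_gene: dict[str, dict] = {}
        for r in filtered:
            g = normalize_symbol(r.gene)
            d = per_gene.setdefault(
                g, {"n_mutations": 0, "n_nonsilent": 0}
            )
            d["n_mutations"] += 1
            if r.variant_classification in NONSILENT_CLASSES:
                d["n_nonsilent"] += 1
        ndriver: dict[str, int] = {}
        nextreme: dict[str, int] = {}
        for c in calls:
            g = normalize_symbol(c.gene)
            ndriver[g] = ndriver.get(g, 0) + int(c.is_driver)
            nextreme[g] = nextreme.get(g, 0) + int(c.is_extreme)

        st = stats.copy()
        st["_norm"] = st["gene"].map(normalize_symbol)
        st = st.set_index("_norm")

        q_map = dict(zip(st.index, st["q_value"]))
        score_df = (
            driverness_scores(
                {g: q_map[g] for g in sorted(q_map)},
                sigma_convention=config.sigma_convention,
            )
            if len(q_map) >= 2
            else pd.DataFrame(columns=["entity", "score"])
        )
        dscore = dict(zip(score_df["entity"], score_df["score"]))

        rows = []
        for t in tiers:
            g = normalize_symbol(t.gene)
            srow = st.loc[g] if g in st.index else None
            rows.append(
                {
                    "gene": t.gene,
                    "n_mutations": per_gene.get(g, {}).get("n_mutations", 0),
                    "n_nonsilent": per_gene.get(g, {}).get("n_nonsilent", 0),
                    "n_driver_mutations": ndriver.get(g, 0),
                    "n_extreme_mutations": nextreme.get(g, 0),
                    "p_mutsig": srow["p_mutsig"] if srow is not None else np.nan,
                    "p_mutpanning": srow["p_mutpanning"] if srow is not None else np.nan,
                    "p_combined": srow["p_combined"] if srow is not None else np.nan,
                    "q_value": srow["q_value"] if srow is not None else np.nan,
                    "consensus_score": t.consensus_score,
                    "level": t.level,
                    "is_driver_gene": t.gene in drivers,
                    "driverness_score": dscore.get(g, np.nan),
                }
            )
        df = pd.DataFrame(rows).sort_values(
            ["is_driver_gene", "consensus_score", "q_value", "gene"],
            ascending=[False, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        return df

    enrichment_table = None
    if config.gmt:
        @stage("enrichment")
        def enrichment_table():
            if not drivers:
                manifest["notes"].append("no driver genes; enrichment skipped")
                return None
            collection = read_gmt(config.gmt)
            if config.background:
                bg = read_gene_list(config.background)
            else:
                bg = sorted({r.gene for r in filtered})
            df = hypergeom_enrich(
                drivers, collection, bg, fdr_threshold=config.fdr_threshold
            )
            if len(df):
                pw_scores = driverness_scores(
                    dict(zip(df["set_id"], df["q_value"].clip(lower=1e-300))),
                    sigma_convention=config.sigma_convention,
                ) if len(df) >= 2 else None
                if pw_scores is not None:
                    df = df.merge(
                        pw_scores[["entity", "score"]].rename(
                            columns={"entity": "set_id", "score": "driverness_score"}
                        ),
                        on="set_id", how="left",
                    )
            counts["pathways_tested"] = len(df)
            counts["pathways_significant"] = int(df["significant"].sum()) if len(df) else 0
            return df
    else:
        manifest["notes"].append("no GMT supplied; enrichment skipped")

    interaction_table = None
    ranked = [
        g for g in gene_table.loc[gene_table["is_driver_gene"], "gene"]
    ]
    if len(ranked) >= 2:
        @stage("interactions")
        def interaction_table():
            df = pairwise_interactions(filtered, ranked, top_k=config.top_k)
            counts["interaction_pairs"] = len(df)
            return df
    else:
        manifest["notes"].append("fewer than two driver genes; interactions skipped")

    drug_gene_table = combination_table = None
    if config.drug_table:
        @stage("druggability")
        def _drug():
            ann = annotate_druggability(
                sorted(drivers, key=normalize_symbol),
                read_drug_table(config.drug_table),
                cohort=filtered,
            )
            counts["actionable_driver_genes"] = int(ann.gene_drugs["actionable"].sum())
            if ann.combination_candidates is not None and len(ann.combination_candidates):
                counts["combination_candidates"] = int(
                    ann.combination_candidates["combination_candidate"].sum()
                )
            return ann
        drug_gene_table = _drug.gene_drugs
        combination_table = _drug.combination_candidates
    else:
        manifest["notes"].append("no drug table supplied; druggability skipped")

    mutation_table = _mutation_table(calls)

    # write everything only after all stages succeeded
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results(mutation_table, out_dir / "mutations.tsv")
    write_results(gene_table, out_dir / "genes.tsv")
    if enrichment_table is not None:
        write_results(enrichment_table, out_dir / "enrichment.tsv")
    if interaction_table is not None:
        write_results(interaction_table, out_dir / "interactions.tsv")
    if drug_gene_table is not None:
        write_results(drug_gene_table, out_dir / "drug_genes.tsv")
    if combination_table is not None:
        write_results(combination_table, out_dir / "combination_candidates.tsv")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return PipelineResult(
        mutation_table=mutation_table,
        gene_table=gene_table,
        enrichment_table=enrichment_table,
        interaction_table=interaction_table,
        drug_gene_table=drug_gene_table,
        combination_table=combination_table,
        driver_genes=set(drivers),
        manifest=manifest,
    )
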