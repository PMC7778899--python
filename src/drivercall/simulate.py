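"""Synthetic somatic-mutation cohorts with planted driver signal.

The generator emulates the statistical structure the driver-calling
rules assume: a passenger background whose per-gene mutation count
scales with coding length, plus designated driver genes that carry a
recurrent identical missense change (a hotspot shared by several
patients) with high ML driver scores and high ReVe scores.  Companion
generators produce driver-set catalogs with configurable coverage of
the planted genes, GMT gene-set collections containing one planted
"true pathway", and small drug-gene tables, so every pipeline stage is
testable without external downloads.

Positions are drawn inside fictive per-gene coordinate blocks on a
single synthetic contig; no reference genome is used, and silent
versus non-silent status is a Bernoulli draw, not codon-modeled.
All outputs are deterministic given the seed: the same config yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import SIGNIFICANCE_SET_NAME
from .io import MutationRecord, records_to_frame, write_results

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_driver_catalog",
    "simulate_gene_sets",
    "simulate_drug_table",
]

_BASES = np.array(list("ACGT"))
_LOF_CLASSES = ("Nonsense_Mutation", "Splice_Site", "Frame_Shift_Del",
                "Frame_Shift_Ins", "Nonstop_Mutation")
_GENE_BLOCK = 100_000  # bp reserved per gene on the synthetic contig
_CONTIG = "chrS"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``background_rate`` is the per-bp, per-sample *non-silent*
    passenger mutation rate (exome-realistic default ~3e-6, i.e. a few
    mutations per Mb); silent passengers are added on top according to
    ``fraction_silent``.  Planted driver genes each receive one
    recurrent missense hotspot shared by ``driver_recurrence`` patients
    plus a Poisson(``extra_driver_rate``) number of additional
    high-score missense singletons.  Beta parameters concentrate driver
    ML scores near 1 and passenger scores near 0.
    """

    n_samples: int = 200
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (1000, 3000)
    background_rate: float = 3e-6
    fraction_silent: float = 0.3
    lof_fraction: float = 0.15        # LoF share of non-silent passengers
    n_planted_drivers: int = 20
    driver_recurrence: int = 5
    extra_driver_rate: float = 2.0
    driver_ai_beta: tuple[float, float] = (60.0, 1.5)
    passenger_ai_beta: tuple[float, float] = (2.0, 10.0)
    driver_reve_beta: tuple[float, float] = (8.0, 2.0)
    passenger_reve_beta: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.extra_driver_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0 <= self.fraction_silent < 1):
            raise ValueError("fraction_silent must lie in [0, 1)")
        if self.n_planted_drivers > self.n_genes:
            raise ValueError("cannot plant more drivers than genes")
        if self.driver_recurrence > self.n_samples:
            raise ValueError(
                f"recurrence target {self.driver_recurrence} exceeds "
                f"cohort size {self.n_samples}"
            )


@dataclass
class SimulatedCohort:
    """Generated cohort plus its ground truth."""

    maf_path: Path
    truth_mutations_path: Path
    truth_genes_path: Path
    gene_lengths_path: Path
    records: list[MutationRecord] = field(repr=False, default_factory=list)
    truth_genes: list[str] = field(default_factory=list)
    truth_mutations: pd.DataFrame | None = None
    gene_lengths: dict[str, int] = field(default_factory=dict)
    config: SimulationConfig | None = None


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _draw_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(np.flatnonzero(_BASES != ref))[rng.integers(3)]]
    return str(ref), str(alt)


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate a MAF-format cohort and its ground-truth tables.

    Writes ``cohort.maf``, ``truth_mutations.tsv``, ``truth_genes.txt``
    and ``gene_lengths.tsv`` under ``out_dir`` and returns the parsed
    artifacts.  The MAF parses with :func:`drivercall.io.read_maf`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes = _gene_names(config.n_genes)
    samples = _sample_ids(config.n_samples)
    lengths = {
        g: int(l)
        for g, l in zip(
            genes,
            rng.integers(config.gene_length_range[0],
                         config.gene_length_range[1] + 1,
                         size=config.n_genes),
        )
    }
    planted = sorted(
        rng.choice(genes, size=config.n_planted_drivers, replace=False).tolist()
    )
    gene_index = {g: i for i, g in enumerate(genes)}

    total_rate = config.background_rate / (1.0 - config.fraction_silent)

    def block_start(g: str) -> int:
        return gene_index[g] * _GENE_BLOCK + 1

    records: list[MutationRecord] = []

    def passenger(sample: str, gene: str) -> MutationRecord:
        pos = int(block_start(gene) + rng.integers(lengths[gene]))
        silent = rng.random() < config.fraction_silent
        if silent:
            vc, vtype = "Silent", "SNP"
            ref, alt = _draw_snv(rng)
            ai = rv = None
        elif rng.random() < config.lof_fraction:
            vc = _LOF_CLASSES[rng.integers(len(_LOF_CLASSES))]
            if vc.startswith("Frame_Shift"):
                vtype = "DEL" if vc.endswith("Del") else "INS"
                ins = str(_BASES[rng.integers(4)])
                ref, alt = ("T" + ins, "T") if vtype == "DEL" else ("T", "T" + ins)
            else:
                vtype = "SNP"
                ref, alt = _draw_snv(rng)
            ai = rv = None
        else:
            vc, vtype = "Missense_Mutation", "SNP"
            ref, alt = _draw_snv(rng)
            ai = float(rng.beta(*config.passenger_ai_beta))
            rv = float(rng.beta(*config.passenger_reve_beta))
        return MutationRecord(
            sample_id=sample, gene=gene, chrom=_CONTIG, pos=pos,
            ref=ref, alt=alt, variant_classification=vc, variant_type=vtype,
            ai_driver_score=ai, reve_score=rv,
        )

    # passenger background: per-sample, per-gene Poisson counts
    for sample in samples:
        for gene in genes:
            n = rng.poisson(total_rate * lengths[gene])
            for _ in range(n):
                records.append(passenger(sample, gene))

    # planted driver hotspots + extra high-score singletons
    truth_rows = []
    for gene in planted:
        pos = int(block_start(gene) + rng.integers(lengths[gene]))
        ref, alt = _draw_snv(rng)
        carriers = rng.choice(samples, size=config.driver_recurrence, replace=False)
        for s in sorted(carriers.tolist()):
            records.append(
                MutationRecord(
                    sample_id=s, gene=gene, chrom=_CONTIG, pos=pos,
                    ref=ref, alt=alt,
                    variant_classification="Missense_Mutation",
                    variant_type="SNP",
                    ai_driver_score=float(rng.beta(*config.driver_ai_beta)),
                    reve_score=float(rng.beta(*config.driver_reve_beta)),
                )
            )
        truth_rows.append(
            {"gene": gene, "chrom": _CONTIG, "pos": pos, "ref": ref,
             "alt": alt, "n_samples_planted": config.driver_recurrence}
        )
        for _ in range(rng.poisson(config.extra_driver_rate)):
            epos = int(block_start(gene) + rng.integers(lengths[gene]))
            eref, ealt = _draw_snv(rng)
            s = samples[rng.integers(config.n_samples)]
            records.append(
                MutationRecord(
                    sample_id=s, gene=gene, chrom=_CONTIG, pos=epos,
                    ref=eref, alt=ealt,
                    variant_classification="Missense_Mutation",
                    variant_type="SNP",
                    ai_driver_score=float(rng.beta(*config.driver_ai_beta)),
                    reve_score=float(rng.beta(*config.driver_reve_beta)),
                )
            )

    maf_path = out_dir / "cohort.maf"
    maf = records_to_frame(records, maf_columns=True)
    with open(maf_path, "w", encoding="utf-8") as fh:
        fh.write("#version synthetic-cohort\n")
        maf.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    truth_mutations = pd.DataFrame(
        truth_rows,
        columns=["gene", "chrom", "pos", "ref", "alt", "n_samples_planted"],
    )
    truth_mutations_path = out_dir / "truth_mutations.tsv"
    write_results(truth_mutations, truth_mutations_path)

    truth_genes_path = out_dir / "truth_genes.txt"
    truth_genes_path.write_text("".join(g + "\n" for g in planted))

    gene_lengths_path = out_dir / "gene_lengths.tsv"
    write_results(
        pd.DataFrame({"gene": genes, "length": [lengths[g] for g in genes]}),
        gene_lengths_path,
    )

    return SimulatedCohort(
        maf_path=maf_path,
        truth_mutations_path=truth_mutations_path,
        truth_genes_path=truth_genes_path,
        gene_lengths_path=gene_lengths_path,
        records=records,
        truth_genes=planted,
        truth_mutations=truth_mutations,
        gene_lengths=lengths,
        config=config,
    )


def simulate_driver_catalog(
    universe: Sequence[str],
    planted_drivers: Sequence[str],
    out_dir: str | Path,
    n_sets: int = 16,
    group1_count: int = 4,
    coverage: float = 0.9,
    decoys_per_set: int = 20,
    seed: int = 0,
    reserve_significance_slot: bool = True,
) -> tuple[dict[str, Path], list[str]]:
    """Write synthetic driver-catalog files with planted-gene coverage.

    Each set contains each planted driver independently with
    probability ``coverage`` plus random decoy genes.  The first
    ``group1_count`` set names are the gold-standard group; when
    ``reserve_significance_slot`` is true one Group1 slot is left for
    the significance-derived set injected at run time, so only
    ``n_sets - 1`` files are written.

    Returns (mapping set name -> file path, list of Group1 names
    including the reserved slot).
    """
    if not (0.0 <= coverage <= 1.0):
        raise ValueError("coverage must lie in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gold = ["CGC", "OncoKB", "MutPanning", "CTAT", "IntOGen", "Bailey2018"]
    n_files_group1 = group1_count - 1 if reserve_significance_slot else group1_count
    group1_file_names = gold[:n_files_group1]
    group1_names = group1_file_names + (
        [SIGNIFICANCE_SET_NAME] if reserve_significance_slot else []
    )
    n_group2 = (n_sets - 1 if reserve_significance_slot else n_sets) - n_files_group1
    names = group1_file_names + [f"DriverSet{j + 1:02d}" for j in range(n_group2)]

    planted = list(planted_drivers)
    decoy_pool = [g for g in universe if g not in set(planted)]
    paths: dict[str, Path] = {}
    for name in names:
        members = [g for g in planted if rng.random() < coverage]
        k = min(decoys_per_set, len(decoy_pool))
        if k:
            members += rng.choice(decoy_pool, size=k, replace=False).tolist()
        p = out_dir / f"{name}.txt"
        p.write_text("".join(m + "\n" for m in members))
        paths[name] = p
    return paths, group1_names


def simulate_gene_sets(
    universe: Sequence[str],
    planted_drivers: Sequence[str],
    out_path: str | Path,
    n_sets: int = 50,
    size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
    true_set_id: str = "TRUE_PATHWAY",
) -> Path:
    """Write a GMT collection with one pathway enriched for the drivers.

    The designated true pathway contains every planted driver plus
    random fillers up to the minimum set size; the remaining sets are
    uniform random draws from the universe.
    """
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("set sizes infeasible for the universe")
    out_path = Path(out_path)
    rng = np.random.default_rng(seed)
    universe = list(universe)
    planted = list(planted_drivers)

    lines = []
    members = list(planted)
    non_planted = [g for g in universe if g not in set(planted)]
    if len(members) < lo:
        members += rng.choice(non_planted, size=lo - len(members), replace=False).tolist()
    lines.append("\t".join([true_set_id, "planted driver pathway"] + members))
    for j in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        mem = rng.choice(universe, size=size, replace=False).tolist()
        lines.append("\t".join([f"SET{j + 1:03d}", f"random set {j + 1}"] + mem))
    out_path.write_text("".join(l + "\n" for l in lines))
    return out_path


def simulate_drug_table(
    actionable_genes: Sequence[str],
    out_path: str | Path,
    drugs_per_gene: int = 2,
    seed: int = 0,
) -> Path:
    """Write a small synthetic drug-gene interaction TSV."""
    rng = np.random.default_rng(seed)
    kinds = ["inhibitor", "antibody", "antagonist"]
    rows = []
    for g in actionable_genes:
        for d in range(drugs_per_gene):
            rows.append(
                {"gene": g, "drug": f"DRUG-{g}-{d + 1}",
                 "interaction_type": kinds[rng.integers(len(kinds))],
                 "source": "synthetic"}
            )
    out_path = Path(out_path)
    write_results(pd.DataFrame(rows, columns=["gene", "drug", "interaction_type", "source"]), out_path)
    return out_path


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable view of a config (for manifests)."""
    return asdict(config)
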