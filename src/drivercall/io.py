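"""Readers and writers for the external formats the pipeline consumes.

Covers MAF-style somatic mutation tables (tab-separated, ``#`` comment
lines, MC3-like column names), plain one-symbol-per-line driver-set
files, GMT gene-set collections, drug-gene interaction tables and the
TSV result tables every stage emits.

Coordinates follow the MAF convention (1-based, inclusive).  Gene
identity is the HUGO symbol string: original case is preserved on the
records, and matching across files is case-insensitive (see
:func:`normalize_symbol`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import DriverSetCatalog, DEFAULT_GROUP1_NAMES

__all__ = [
    "MutationRecord",
    "GeneSetCollection",
    "DrugGeneTable",
    "MafFormatError",
    "VARIANT_CLASSIFICATIONS",
    "normalize_symbol",
    "read_maf",
    "records_to_frame",
    "read_driver_sets",
    "read_gmt",
    "read_drug_table",
    "read_pvalue_table",
    "read_gene_list",
    "write_results",
]

#: MAF controlled vocabulary for Variant_Classification (MC3 dialect).
VARIANT_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Splice_Region",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Silent",
        "Translation_Start_Site",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "RNA",
        "IGR",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)

MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
)

#: Default names of the extra per-mutation pathogenicity score columns.
DEFAULT_SCORE_COLUMNS = {
    "ai_driver_score": "AI_Driver_score",
    "reve_score": "ReVe_score",
}


class MafFormatError(ValueError):
    """Raised when a MAF (or other tabular input) violates the format."""


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol for cross-file matching."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant observed in one tumor sample.

    Pathogenicity scores are optional: ``ai_driver_score`` is the
    machine-learning driver probability of a missense change and
    ``reve_score`` the combined missense pathogenicity score, both in
    [0, 1] when present.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_classification: str
    variant_type: str = "SNP"
    protein_change: str | None = None
    ai_driver_score: float | None = None
    reve_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.variant_type == "SNP" and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError(
                f"SNP alleles must be single bases, got {self.ref!r}>{self.alt!r}"
            )
        if self.variant_classification not in VARIANT_CLASSIFICATIONS:
            raise ValueError(
                f"unknown Variant_Classification {self.variant_classification!r}"
            )
        for name in ("ai_driver_score", "reve_score"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic identity of the change: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneSetCollection:
    """Flat gene-set collection (GO/KEGG-style), keyed by set id."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    source_tag: str = "custom"

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


@dataclass
class DrugGeneTable:
    """Drug-gene interaction rows: (gene, drug, interaction type, source)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "drug"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"drug table missing columns: {sorted(missing)}")
        if (self.table["gene"].astype(str).str.strip() == "").any():
            raise ValueError("drug table contains empty gene symbols")

    def genes(self) -> set[str]:
        return {normalize_symbol(g) for g in self.table["gene"]}


def _score_from_row(value: object) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", ".", "NA", "NaN"):
            return None
        value = float(value)
    return float(value)


def read_maf(
    path: str | Path,
    score_columns: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Read a MAF file into a list of :class:`MutationRecord`.

    Parameters
    ----------
    path:
        Tab-separated MAF file; lines beginning with ``#`` are skipped.
    score_columns:
        Optional mapping from record field (``ai_driver_score``,
        ``reve_score``) to the column name carrying it.  Defaults to
        ``AI_Driver_score`` / ``ReVe_score``; absent columns simply
        yield records without scores.
    """
    path = Path(path)
    cols = dict(DEFAULT_SCORE_COLUMNS)
    if score_columns:
        cols.update(score_columns)

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in MAF_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise MafFormatError(f"{path}: missing mandatory MAF column {col!r}")

    positions = pd.to_numeric(df["Start_Position"], errors="coerce")
    bad = positions.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based data line, after the header
        raise MafFormatError(
            f"{path}: unparseable Start_Position "
            f"{df.loc[bad.idxmax(), 'Start_Position']!r} at data line {row}"
        )

    has_vt = "Variant_Type" in df.columns
    has_hgvsp = "HGVSp_Short" in df.columns
    ai_col = cols["ai_driver_score"] if cols["ai_driver_score"] in df.columns else None
    reve_col = cols["reve_score"] if cols["reve_score"] in df.columns else None

    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False, name=None)):
        d = dict(zip(df.columns, row))
        try:
            records.append(
                MutationRecord(
                    sample_id=d["Tumor_Sample_Barcode"],
                    gene=d["Hugo_Symbol"],
                    chrom=d["Chromosome"],
                    pos=int(positions.iloc[i]),
                    ref=d["Reference_Allele"],
                    alt=d["Tumor_Seq_Allele2"],
                    variant_classification=d["Variant_Classification"],
                    variant_type=d["Variant_Type"] if has_vt else _infer_type(d),
                    protein_change=d["HGVSp_Short"] or None if has_hgvsp else None,
                    ai_driver_score=_score_from_row(d[ai_col]) if ai_col else None,
                    reve_score=_score_from_row(d[reve_col]) if reve_col else None,
                )
            )
        except ValueError as exc:
            raise MafFormatError(f"{path}: data line {i + 2}: {exc}") from exc
    return records


def _infer_type(d: Mapping[str, str]) -> str:
    ref, alt = d["Reference_Allele"], d["Tumor_Seq_Allele2"]
    if len(ref) == len(alt) == 1 and ref != "-" and alt != "-":
        return "SNP"
    if ref == "-" or len(alt) > len(ref):
        return "INS"
    return "DEL"


# Columns retained when a cohort is written back out as a MAF.
_MAF_EXPORT_COLUMNS = {
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Classification": "variant_classification",
    "Variant_Type": "variant_type",
    "Tumor_Sample_Barcode": "sample_id",
    "HGVSp_Short": "protein_change",
    "AI_Driver_score": "ai_driver_score",
    "ReVe_score": "reve_score",
}


def records_to_frame(records: Iterable[MutationRecord], maf_columns: bool = False) -> pd.DataFrame:
    """Tabulate mutation records; ``maf_columns=True`` uses MAF headers."""
    rows = [vars(r) if not isinstance(r, dict) else r for r in records]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=list(_MAF_EXPORT_COLUMNS.values()))
    if maf_columns:
        df = df.rename(columns={v: k for k, v in _MAF_EXPORT_COLUMNS.items()})
        df = df[[c for c in _MAF_EXPORT_COLUMNS if c in df.columns]]
    return df


def read_driver_sets(
    paths: Mapping[str, str | Path],
    group1_names: Sequence[str] | None = None,
) -> DriverSetCatalog:
    """Load one gene-list file per driver catalog into a weighted catalog.

    Sets named in ``group1_names`` (default: the four gold-standard
    catalogs) get weight 10; all other sets get weight 1.  Duplicate
    symbols inside a file are silently de-duplicated; an empty file
    produces a warning but the set is retained empty.
    """
    group1 = set(group1_names if group1_names is not None else DEFAULT_GROUP1_NAMES)
    unknown = group1 - set(paths)
    # names reserved for later injection (e.g. the significance-derived
    # set) are allowed to be absent from the file mapping
    catalog = DriverSetCatalog(group1_names=tuple(sorted(group1)))
    for name, p in paths.items():
        members = []
        for line in Path(p).read_text().splitlines():
            sym = line.strip()
            if sym:
                members.append(sym)
        if not members:
            warnings.warn(f"driver set {name!r} ({p}) is empty", stacklevel=2)
        catalog.add_set(name, members, group1=name in group1)
    del unknown
    return catalog


def read_gmt(path: str | Path, source_tag: str = "custom") -> GeneSetCollection:
    """Parse a GMT file: ``set_id TAB description TAB member...`` per line."""
    path = Path(path)
    coll = GeneSetCollection(source_tag=source_tag)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise MafFormatError(
                f"{path}: line {lineno}: GMT line needs >=3 tab-separated fields"
            )
        set_id, desc, *members = fields
        if set_id in coll.sets:
            raise MafFormatError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
        members = [m for m in members if m.strip()]
        if not members:
            raise MafFormatError(f"{path}: line {lineno}: set {set_id!r} has no members")
        coll.sets[set_id] = (desc, frozenset(normalize_symbol(m) for m in members))
    return coll


def read_drug_table(path: str | Path) -> DrugGeneTable:
    """Read a drug-gene interaction TSV (DGIdb-style export).

    Accepts either the canonical columns ``gene/drug/interaction_type/
    source`` or the DGIdb export names (``gene_name``, ``drug_name``,
    ``interaction_types``, ``interaction_claim_source``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    aliases = {
        "gene_name": "gene",
        "drug_name": "drug",
        "interaction_types": "interaction_type",
        "interaction_claim_source": "source",
    }
    df = df.rename(columns={c: aliases.get(c, c) for c in df.columns})
    for col in ("interaction_type", "source"):
        if col not in df.columns:
            df[col] = ""
    return DrugGeneTable(df[["gene", "drug", "interaction_type", "source"]])


def read_pvalue_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (gene, p) TSV with a header into a mapping."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise MafFormatError(f"{path}: p-value table needs two columns (gene, p)")
    genes = df.iloc[:, 0].astype(str)
    pvals = pd.to_numeric(df.iloc[:, 1], errors="raise")
    return dict(zip(genes, pvals.astype(float)))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain one-symbol-per-line gene list (order preserved)."""
    return [s.strip() for s in Path(path).read_text().splitlines() if s.strip()]


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as tab-separated UTF-8 with a header row.

    Floats are rendered with 8 significant digits so values survive a
    write/read round trip at working precision.
    """
    records.to_csv(path, sep="\t", index=False, float_format="%.8g", encoding="utf-8")
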