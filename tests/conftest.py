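from __future__ import annotations

from pathlib import Path

import pytest

from drivercall.io import MutationRecord


def make_record(
    sample_id="S1",
    gene="TP53",
    chrom="chr17",
    pos=7577120,
    ref="C",
    alt="T",
    variant_classification="Missense_Mutation",
    variant_type="SNP",
    **kwargs,
) -> MutationRecord:
    return MutationRecord(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref,
        alt=alt, variant_classification=variant_classification,
        variant_type=variant_type, **kwargs,
    )


MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tVariant_Type\t"
    "Tumor_Sample_Barcode\tAI_Driver_score\tReVe_score"
)


def maf_line(gene, chrom, pos, ref, alt, vc, vt, sample, ai="", reve=""):
    return "\t".join(map(str, [gene, chrom, pos, ref, alt, vc, vt, sample, ai, reve]))


@pytest.fixture
def toy_maf(tmp_path) -> Path:
    """Three fully-populated missense rows."""
    lines = [
        MAF_HEADER,
        maf_line("TP53", "chr17", 7577120, "C", "T", "Missense_Mutation", "SNP", "S1", 0.98, 0.91),
        maf_line("KRAS", "chr12", 25398284, "C", "A", "Missense_Mutation", "SNP", "S2", 0.99, 0.88),
        maf_line("BRAF", "chr7", 140453136, "A", "T", "Missense_Mutation", "SNP", "S3", 0.97, 0.76),
    ]
    p = tmp_path / "toy.maf"
    p.write_text("\n".join(lines) + "\n")
    return p
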