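"""Mutation-level classification: driver and extreme calls, ReVe
percentiles, Ti/Tv classes and hypermutator filtering.

Two independent rules operate at the mutation level:

* an *extreme* mutation is a loss-of-function change (stop-gain,
  stop-loss, splice site, frameshift indel) or a missense change with
  ReVe score >= 0.5;
* a *driver* mutation is a missense change with a machine-learning
  driver score >= 0.95 observed in at least two patients of the cohort.

Recurrence identity is the exact genomic change (chrom, pos, ref, alt);
patients are distinct tumor sample barcodes.  Neither rule implies the
other: the driver rule uses the ML score, the extreme rule uses ReVe.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import MutationRecord

__all__ = [
    "LOF_CLASSES",
    "MISSENSE_CLASS",
    "MutationCall",
    "TiTv",
    "classify_extreme",
    "call_driver_mutations",
    "reve_percentile",
    "classify_titv",
    "filter_hypermutated",
]

#: Loss-of-function MAF classes (stop-gain, stop-loss, splice-site SNVs,
#: frameshift indels).  Splice detection relies on the MAF term only.
LOF_CLASSES = frozenset(
    {"Nonsense_Mutation", "Nonstop_Mutation", "Splice_Site",
     "Frame_Shift_Del", "Frame_Shift_Ins"}
)

MISSENSE_CLASS = "Missense_Mutation"

#: Classes counted as non-silent for burden and interaction analyses.
NONSILENT_CLASSES = LOF_CLASSES | {
    MISSENSE_CLASS, "In_Frame_Del", "In_Frame_Ins", "Translation_Start_Site",
}


@dataclass(frozen=True)
class MutationCall:
    """One distinct genomic change aggregated over the cohort."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_classification: str
    n_patients: int
    max_ai_driver: float | None
    max_reve: float | None
    is_driver: bool
    is_extreme: bool
    reve_percentile: float | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def classify_extreme(record: MutationRecord, reve_threshold: float = 0.5) -> bool:
    """Whether a single variant is an extreme (LoF-or-deleterious) mutation.

    True for loss-of-function classes regardless of scores, and for
    missense changes with ReVe score >= ``reve_threshold`` (boundary
    inclusive).  A missense record without a ReVe score is not extreme.
    """
    vc = record.variant_classification
    if vc in LOF_CLASSES:
        return True
    if vc == MISSENSE_CLASS and record.reve_score is not None:
        return record.reve_score >= reve_threshold
    return False


def call_driver_mutations(
    cohort: Iterable[MutationRecord],
    score_threshold: float = 0.95,
    min_recurrence: int = 2,
    reve_threshold: float = 0.5,
) -> list[MutationCall]:
    """Aggregate a cohort into per-change calls with driver/extreme flags.

    Mutations are grouped by exact genomic identity; ``n_patients`` is
    the number of distinct sample barcodes carrying the change.  The
    driver flag requires a missense class, maximum ML driver score >=
    ``score_threshold`` and recurrence in >= ``min_recurrence``
    patients.  ReVe percentiles are assigned across all calls carrying
    a ReVe score (average rank / n, so the top score maps to 1.0).
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    groups: dict[tuple[str, int, str, str], list[MutationRecord]] = defaultdict(list)
    for rec in cohort:
        groups[rec.key].append(rec)

    calls: list[MutationCall] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2], k[3])):
        recs = groups[key]
        first = recs[0]
        n_patients = len({r.sample_id for r in recs})
        ai = [r.ai_driver_score for r in recs if r.ai_driver_score is not None]
        rv = [r.reve_score for r in recs if r.reve_score is not None]
        max_ai = max(ai) if ai else None
        max_rv = max(rv) if rv else None
        is_driver = (
            first.variant_classification == MISSENSE_CLASS
            and max_ai is not None
            and max_ai >= score_threshold
            and n_patients >= min_recurrence
        )
        is_extreme = any(classify_extreme(r, reve_threshold) for r in recs)
        calls.append(
            MutationCall(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                gene=first.gene,
                variant_classification=first.variant_classification,
                n_patients=n_patients,
                max_ai_driver=max_ai,
                max_reve=max_rv,
                is_driver=is_driver,
                is_extreme=is_extreme,
            )
        )

    scored = [i for i, c in enumerate(calls) if c.max_reve is not None]
    if scored:
        pct = reve_percentile([calls[i].max_reve for i in scored])
        for i, p in zip(scored, pct):
            c = calls[i]
            calls[i] = MutationCall(
                **{**vars(c), "reve_percentile": float(p)}
            )
    return calls


def reve_percentile(scores: Sequence[float]) -> np.ndarray:
    """Rank percentiles of pathogenicity scores in (0, 1].

    percentile(s) = rank(s) / n, where a group of tied scores shares
    the rank of its lowest member (one more than the count of strictly
    smaller scores).  An untied maximum maps to exactly 1.0 and the
    ordering is preserved.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one score")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    return rankdata(arr, method="min") / arr.size


class TiTv(NamedTuple):
    conversion: str      # one of C>A, C>G, C>T, T>A, T>C, T>G
    is_transition: bool


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITIONS = {"C>T", "T>C"}


def classify_titv(record: MutationRecord) -> TiTv:
    """Pyrimidine-collapsed substitution class of a SNP.

    Purine-reference changes are complemented into the six canonical
    classes (e.g. G>A becomes C>T); transitions are C>T and T>C.
    """
    if record.variant_type != "SNP":
        raise ValueError(f"Ti/Tv is defined for SNPs only, got {record.variant_type}")
    ref, alt = record.ref.upper(), record.alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT alleles {ref!r}>{alt!r}")
    if ref in "AG":  # collapse purine reference onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    conv = f"{ref}>{alt}"
    return TiTv(conversion=conv, is_transition=conv in _TRANSITIONS)


def filter_hypermutated(
    cohort: Iterable[MutationRecord],
    max_mutations_per_sample: int,
) -> tuple[list[MutationRecord], list[str]]:
    """Drop samples whose total mutation count exceeds the cap.

    The rule is strictly greater-than: a sample with exactly
    ``max_mutations_per_sample`` mutations is retained.  Returns the
    retained records and the sorted list of removed sample barcodes.
    """
    if max_mutations_per_sample < 1:
        raise ValueError("max_mutations_per_sample must be >= 1")
    cohort = list(cohort)
    counts: dict[str, int] = defaultdict(int)
    for rec in cohort:
        counts[rec.sample_id] += 1
    removed = {s for s, n in counts.items() if n > max_mutations_per_sample}
    retained = [r for r in cohort if r.sample_id not in removed]
    return retained, sorted(removed)
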