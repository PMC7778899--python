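"""Call driver and extreme mutations in a tiny hand-built cohort.

A driver mutation is a missense change with ML driver score >= 0.95
seen in at least two patients; an extreme mutation is a
loss-of-function change or a missense with ReVe >= 0.5.
"""

from drivercall import MutationRecord, call_driver_mutations, classify_titv

cohort = [
    # the same KRAS hotspot in three patients, high driver scores
    MutationRecord("PT01", "KRAS", "chr12", 25398284, "C", "A",
                   "Missense_Mutation", ai_driver_score=0.99, reve_score=0.93),
    MutationRecord("PT02", "KRAS", "chr12", 25398284, "C", "A",
                   "Missense_Mutation", ai_driver_score=0.97, reve_score=0.90),
    MutationRecord("PT03", "KRAS", "chr12", 25398284, "C", "A",
                   "Missense_Mutation", ai_driver_score=0.98, reve_score=0.91),
    # a TP53 stop-gain: extreme by class, never a driver call (not missense)
    MutationRecord("PT02", "TP53", "chr17", 7578190, "G", "A",
                   "Nonsense_Mutation"),
    # a singleton high-score missense: recurrence below 2, not a driver
    MutationRecord("PT04", "EGFR", "chr7", 55259515, "T", "G",
                   "Missense_Mutation", ai_driver_score=0.99, reve_score=0.40),
]

for call in call_driver_mutations(cohort):
    titv = classify_titv(cohort[0]) if call.gene == "KRAS" else None
    print(f"{call.gene:5s} {call.chrom}:{call.pos} {call.ref}>{call.alt} "
          f"patients={call.n_patients} driver={call.is_driver} "
          f"extreme={call.is_extreme}")

print()
print("KRAS substitution class:", classify_titv(cohort[0]))
# Expected: the recurrent KRAS change is the only driver call; the TP53
# stop-gain is extreme; the EGFR singleton is neither.  The KRAS C>A
# change is a transversion.
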