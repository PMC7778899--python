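"""Gaussian driverness scores and hypergeometric pathway enrichment.

The driverness score of an entity is Phi((x - mu) / sigma) with
x = -log2(FDR), standardized within its entity class; pathway
enrichment is the upper hypergeometric tail of the driver-gene overlap
with each set, BH-corrected.
"""

from drivercall import driverness_scores, hypergeom_enrich
from drivercall.io import GeneSetCollection

scores = driverness_scores({"TP53": 0.001, "KRAS": 0.01, "GENEX": 0.4})
print(scores.to_string(index=False))
# x = -log2(FDR); TP53 has the smallest FDR hence the highest score.

background = [f"G{i:02d}" for i in range(30)] + ["TP53", "KRAS", "BRAF", "EGFR"]
collection = GeneSetCollection(sets={
    "PW1": ("MAPK-like pathway", frozenset({"TP53", "KRAS", "BRAF", "G01"})),
    "PW2": ("random pathway", frozenset({"G05", "G06", "G07", "G08"})),
})
drivers = ["TP53", "KRAS", "BRAF"]

result = hypergeom_enrich(drivers, collection, background)
print()
print(result[["set_id", "k", "K", "n", "N", "p_value", "q_value",
              "significant"]].to_string(index=False))
# PW1 contains all three drivers out of a 4-gene set in a 34-gene
# universe -> tiny p; PW2 overlaps nothing -> p = 1.
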