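"""Rank genes: combine two significance streams, vote over driver
catalogs, and assign five-tier pathogenicity levels.

Per gene, p-values from a coverage-aware recurrence test and a
positional-clustering test are combined with Fisher's method and
BH-corrected; genes at FDR <= 0.05 form a significance-derived driver
set that joins the catalog vote (Group1 sets weigh 10, Group2 weigh 1;
Level 4 means consensus score >= 20).
"""

from drivercall import DriverSetCatalog, combine_gene_pvalues, significant_genes
from drivercall.genes import classify_tiers, inject_significance_set

p_recurrence = {"TP53": 1e-8, "KRAS": 1e-6, "GENEX": 0.20, "GENEY": 0.80}
p_positional = {"TP53": 1e-5, "KRAS": 1e-7, "GENEX": 0.35, "GENEY": 0.60}

stats = combine_gene_pvalues(p_recurrence, p_positional)
print(stats.to_string(index=False))

catalog = DriverSetCatalog(group1_names=("CGC", "OncoKB", "AI-DriverGene"))
catalog.add_set("CGC", ["TP53", "KRAS"])
catalog.add_set("OncoKB", ["KRAS"])
catalog.add_set("PanelA", ["TP53", "GENEX"], group1=False)

sig = significant_genes(stats, fdr_threshold=0.05)
inject_significance_set(catalog, sig)
print("\nsignificance-derived set:", sorted(sig))

for t in classify_tiers(["TP53", "KRAS", "GENEX", "GENEY"], catalog):
    print(f"{t.gene:6s} consensus={t.consensus_score:2d} level={t.level}")
# TP53 and KRAS clear FDR 0.05, so each gains the injected Group1 set:
# TP53 = CGC(10) + PanelA(1) + injected(10) = 21 -> Level 4;
# KRAS = CGC + OncoKB + injected = 30 -> Level 4; GENEX = 1 -> Level 1.
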