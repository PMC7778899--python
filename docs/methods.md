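# Methods

## Model and procedure

`drivercall` treats driver discovery as evidence aggregation at three
levels.

**Mutations.** Somatic variants are grouped by exact genomic identity
(chrom, pos, ref, alt); per-gene or per-codon collapsing is
deliberately not used, because recurrence of the identical change is
the strongest single signal of positive selection and the natural unit
for hotspot lookup. Patients are distinct tumor sample barcodes;
multi-aliquot patients are not collapsed. The driver rule (missense,
ML score ≥ 0.95, ≥ 2 patients) and the extreme rule (LoF class, or
missense ReVe ≥ 0.5, boundaries inclusive) are independent by design:
one is driven by the ML driver probability, the other by the
pathogenicity score, so neither set needs to contain the other. ReVe
scores are additionally reported as rank percentiles, rank/n where a
tied group shares the rank of its lowest member; this is a
presentation transform only — the extreme rule always evaluates the
raw score. Splice-site status is taken from the MAF
`Variant_Classification` term; no distance-to-junction logic is
applied.

**Genes.** The two significance streams are combined per gene with
Fisher's method; with two p-values the χ²₄ upper tail has the exact
closed form e^(−X/2)(1 + X/2), which is what the implementation
computes (unit tests verify agreement with the generic χ² survival
function to 1e−12). p-values are floored at 1e−300 before the
logarithm so that underflowed zeros remain finite. A gene covered by
only one stream keeps that stream's p-value (the missing stream is
treated as 1.0) and is flagged `single_method`. BH correction is
applied within one cohort; a pan-cancer analysis is a separate run on
the pooled MAF. The significance-derived set (FDR ≤ 0.05, inclusive)
is injected into the driver-set catalog as a Group1 member *before*
consensus scoring, so the vote always reflects the current cohort's
own statistics. Consensus scores are integers by construction
(weights 10 and 1), which makes the tier boundaries exact; the tier
map is Level 0 ↔ 0, Level 1 ↔ 1, Level 2 ↔ (1, 10], Level 3 ↔
(10, 20), Level 4 ↔ [20, ∞).

**Driverness scores.** For a class of entities with FDRs, x =
−log₂(FDR) is standardized within the class and mapped through the
standard normal CDF. The standard deviation uses the population
convention (divide by n); on the small entity sets typical of one
cohort this is deterministic and avoids the n−1 blow-up at n = 2, and
a `sigma_convention="sample"` switch is exposed for users who prefer
the unbiased estimator. Entity classes are never pooled: genes are
standardized against genes of the same cohort, pathways against
pathways. Degenerate inputs are defined, not fatal: FDR = 1 gives
x = 0 (a valid minimum), FDR = 0 is floored to 1e−300 with a warning,
all-equal FDRs give σ = 0 and every score 0.5 with a warning; a
single-entity class is an error because standardization is undefined.

**Pathways.** Enrichment is the upper hypergeometric tail of the
driver-gene overlap with each set, after intersecting sets with the
background universe. The default background is all genes observed in
the cohort's MAF ("sequenced at sufficient depth" has no operational
definition without coverage data); it can be overridden by file. Sets
with fewer than 3 or more than 5000 background members are skipped —
conventional enrichment hygiene that keeps q-values from being driven
by untestable sets. GO/KEGG-style collections are treated as flat; no
parent-term propagation is performed. All sets in one supplied
collection are corrected jointly.

**Interactions.** Pairwise mutual exclusivity / co-occurrence uses the
two-sided Fisher exact test (point-probability rule) on per-sample
non-silent mutation status among the top-50 ranked drivers. Direction
comes from the sample odds ratio with 0 and ∞ permitted; a gene
mutated in zero samples yields p = 1 and direction `ns`. Labels follow
the conventional raw-p thresholds 0.05 and 0.01; a BH column is
emitted additionally for users who want FDR control over the
C(50, 2) = 1225 pairs.

**Druggability.** A left join of driver genes onto a drug–gene
interaction table; "actionable" means any table entry (evidence levels
are not modeled). Samples non-silently mutated in ≥ 2 actionable
driver genes are flagged as combination-therapy candidates.

## Gene identity and file handling

Gene identity is the HUGO symbol string; original case is preserved in
outputs, and all cross-file matching is case-insensitive, because
catalog files and MAFs mix cases in the wild. MAF coordinates are
1-based inclusive; only `Tumor_Seq_Allele2` is read as the alternate
allele. The per-mutation score columns default to `AI_Driver_score`
and `ReVe_score` and are remappable, since no standard MAF dialect
defines them. Result TSVs render floats at 8 significant digits so
values round-trip at working precision.

## The synthetic cohorts

`simulate_cohort` emulates exactly the structure the calling rules
assume: passenger counts per sample and gene are Poisson with mean
proportional to coding length at a per-bp non-silent rate (default
3e−6, i.e. a few mutations per megabase — typical exome burden);
silent status is a Bernoulli draw (default 30%); a configurable
fraction of non-silent passengers are LoF classes. Passenger missense
scores come from Beta(2, 10) (concentrated near 0), planted driver
scores from Beta(60, 1.5) for the ML score and Beta(8, 2) for ReVe.
Each planted driver gene receives one recurrent missense hotspot
shared by 5 patients (default) plus ~2 additional high-score
singletons. Positions live in fictive 100-kb per-gene blocks on a
single synthetic contig. Everything is drawn from one
`numpy.random.default_rng(seed)`; identical configs give
byte-identical files.

The standard recovery scenario is 200 samples × 500 genes with 20
planted drivers and driver-catalog coverage 0.9 — small enough to run
in under a second, large enough that the binomial stand-in separates
planted genes from background cleanly.

What the generator does **not** emulate: trinucleotide mutational
signatures, codon structure (silent/non-silent is not
sequence-derived), copy-number and rearrangement events, coverage
variation, expression- or replication-timing-dependent background
rates, and correlated mutation processes across genes. Passing the
recovery tests therefore shows the pipeline's rules and statistics are
implemented correctly and are mutually consistent — it does not show
that the binomial stand-in would rank genes well on real tumors, which
is exactly why production runs consume MutSigCV/MutPanning-style
p-values as inputs.

## The stand-in gene test

`frequency_pvalue_standin` is a deliberately simple upper-tail
binomial test of each gene's non-silent count against
rate × length × n_samples opportunities at the cohort-wide per-bp
rate. It models no covariates and is not a MutSigCV or MutPanning
replacement; it exists so synthetic end-to-end runs have a live
significance stream. Being an exact discrete test, its null p-values
are super-uniform (stochastically larger than uniform) when per-gene
expected counts are small — the p-value distribution has atoms, so a
KS test against Uniform(0, 1) rejects even though the test is valid
and conservative. Null-calibration checks therefore use a pooled-scale
cohort (4000 samples × 200 genes at the default rate, per-gene
expectation ≈ 30) where discreteness is negligible; this mirrors the
pan-cancer regime in which frequency-based tests are actually
deployed.

## Numerical choices and problem sizes

- p-value floor 1e−300 before logs (Fisher combination) and before
  −log₂ (driverness scores).
- BH is the statsmodels step-up implementation behind `bh_correct`,
  verified against a literal step-up oracle.
- Two-sided Fisher p-values are scipy's exact implementation, verified
  against full hypergeometric enumeration on cohorts ≤ 30 samples.
- Enrichment results sort by (q, p, set_id) with a stable sort;
  mutation calls sort by genomic key — ties never reorder between
  runs.
- The test suite and acceptance script use desk-scale problem sizes
  (cohorts of 40–4000 samples, 40–500 genes, five-seed replication),
  chosen so the full suite runs in seconds while keeping every
  statistical check well-powered.

## Known limitations

- The hypermutator filter is a configurable count cap (default 1000
  mutations/sample, strictly-greater rule); no ploidy- or
  MSI-informed curation is attempted.
- The consensus vote treats catalogs as exchangeable within a group;
  per-set reliability weights beyond the 10/1 partition are not
  modeled.
- Pairwise interaction labels use raw p thresholds (with a BH column
  provided); sets of > 2 genes are out of scope.
- Mutation-level FDRs are not derived (no per-mutation significance
  model), so driverness scores are computed for the gene and pathway
  classes in the pipeline; the scoring function itself accepts any
  FDR-bearing entity class.
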