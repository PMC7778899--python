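from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from drivercall.catalog import DriverSetCatalog
from drivercall.genes import (
    annotate_druggability,
    bh_correct,
    combine_gene_pvalues,
    consensus_score,
    finalize_driver_genes,
    fisher_combine,
    frequency_pvalue_standin,
    significant_genes,
    tier_classify,
    classify_tiers,
)
from drivercall.io import DrugGeneTable
from drivercall.mutations import call_driver_mutations
from tests.conftest import make_record


def bh_bruteforce(pvals):
    """Literal step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        q[idx] = running
    return q


class TestFisherCombine:
    def test_null_inputs_combine_to_one(self):
        assert fisher_combine(1.0, 1.0) == 1.0

    def test_hand_computed_values(self):
        assert fisher_combine(0.01, 0.01) == pytest.approx(1.0210e-3, rel=1e-4)
        assert fisher_combine(0.05, 1.0) == pytest.approx(0.19979, rel=1e-4)

    def test_matches_chi_square_df4_upper_tail(self):
        ps = np.geomspace(1e-12, 1.0, 25)
        for p1 in ps:
            for p2 in ps:
                x = -2 * (math.log(p1) + math.log(p2))
                assert fisher_combine(p1, p2) == pytest.approx(
                    chi2.sf(x, df=4), abs=1e-12)

    def test_symmetry_and_monotonicity(self):
        grid = np.geomspace(1e-10, 1.0, 15)
        for a in grid:
            for b in grid:
                assert fisher_combine(a, b) == fisher_combine(b, a)
        fixed = 0.3
        vals = [fisher_combine(p, fixed) for p in grid]
        assert all(x <= y + 1e-15 for x, y in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_combine(bad, 0.5)


class TestBhCorrect:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_correct([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04])

    def test_singleton_passthrough(self):
        np.testing.assert_allclose(bh_correct([1.0]), [1.0])

    def test_never_below_input_and_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 51)))
            q = bh_correct(p)
            assert np.all(q >= p - 1e-15) and np.all(q <= 1)
            np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)


class TestSignificantGenes:
    def _stats(self, qmap):
        return pd.DataFrame({"gene": list(qmap), "q_value": list(qmap.values())})

    def test_threshold_boundary_inclusive(self):
        got = significant_genes(self._stats({"A": 0.01, "B": 0.05, "C": 0.06}))
        assert got == {"A", "B"}

    def test_all_null_gives_empty_set(self):
        assert significant_genes(self._stats({"A": 1.0, "B": 1.0})) == set()

    def test_threshold_one_keeps_everything(self):
        assert significant_genes(self._stats({"A": 0.9, "B": 1.0}), 1.0) == {"A", "B"}


class TestConsensusAndTiers:
    def _catalog(self, memberships):
        cat = DriverSetCatalog(group1_names=("G1a", "G1b", "G1c", "G1d"))
        for name, members in memberships.items():
            cat.add_set(name, members)
        return cat

    def test_two_gold_standard_sets_give_twenty(self):
        cat = self._catalog({"G1a": ["TP53"], "G1b": ["TP53"], "X": ["KRAS"]})
        assert consensus_score("TP53", cat) == 20

    def test_full_membership_gives_fifty_two(self):
        names = ["G1a", "G1b", "G1c", "G1d"] + [f"S{i}" for i in range(12)]
        cat = self._catalog({n: ["EGFR"] for n in names})
        assert consensus_score("EGFR", cat) == 52

    def test_uncovered_gene_scores_zero(self):
        assert consensus_score("NOPE", self._catalog({"G1a": ["TP53"]})) == 0

    def test_matching_is_case_insensitive(self):
        cat = self._catalog({"G1a": ["tp53"]})
        assert consensus_score("TP53", cat) == 10

    def test_random_catalogs_match_naive_membership_sum(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(40)]
        for _ in range(25):
            n_sets = int(rng.integers(1, 17))
            names = [f"SET{j}" for j in range(n_sets)]
            g1 = set(rng.choice(names, size=min(4, n_sets), replace=False))
            cat = DriverSetCatalog(group1_names=tuple(g1))
            member = {}
            for n in names:
                member[n] = set(rng.choice(genes, size=int(rng.integers(0, 20)),
                                           replace=False))
                cat.add_set(n, member[n])
            for g in genes:
                naive = sum((10 if n in g1 else 1) for n in names if g in member[n])
                assert consensus_score(g, cat) == naive

    @pytest.mark.parametrize("score,level", [
        (0, 0), (1, 1), (2, 2), (10, 2), (11, 3), (15, 3), (19, 3),
        (20, 4), (52, 4),
    ])
    def test_tier_boundaries(self, score, level):
        assert tier_classify(score) == level

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            tier_classify(-1)

    def test_every_level_reachable_from_scores_0_to_52(self):
        assert {tier_classify(s) for s in range(53)} == {0, 1, 2, 3, 4}

    def test_adding_gene_to_a_set_never_lowers_its_level(self):
        cat = self._catalog({"G1a": ["A"], "S1": ["A", "B"]})
        before = {g: tier_classify(consensus_score(g, cat)) for g in "AB"}
        cat.add_set("S1", ["A", "B"])           # unchanged
        cat.add_set("G1b", ["B"])               # B gains a Group1 set
        after = {g: tier_classify(consensus_score(g, cat)) for g in "AB"}
        assert all(after[g] >= before[g] for g in "AB")


class TestFinalizeDriverGenes:
    def _calls(self, gene, vc="Missense_Mutation", ai=0.99, n=2):
        recs = [make_record(sample_id=f"S{i}", gene=gene, pos=77,
                            variant_classification=vc,
                            variant_type="SNP",
                            ai_driver_score=ai if vc == "Missense_Mutation" else None)
                for i in range(n)]
        return call_driver_mutations(recs)

    def test_level4_gene_with_driver_mutation_retained(self):
        tiers = classify_tiers(["TP53"], _cat20("TP53"))
        assert finalize_driver_genes(tiers, self._calls("TP53")) == {"TP53"}

    def test_level4_gene_with_only_silent_mutations_dropped(self):
        tiers = classify_tiers(["TP53"], _cat20("TP53"))
        calls = self._calls("TP53", vc="Silent", ai=None)
        assert finalize_driver_genes(tiers, calls) == set()

    def test_level3_gene_dropped_despite_driver_mutations(self):
        cat = DriverSetCatalog(group1_names=("G1a",))
        cat.add_set("G1a", ["TP53"])
        for j in range(5):
            cat.add_set(f"S{j}", ["TP53"], group1=False)
        tiers = classify_tiers(["TP53"], cat)  # score 15, level 3
        assert tiers[0].level == 3
        assert finalize_driver_genes(tiers, self._calls("TP53")) == set()


def _cat20(gene):
    cat = DriverSetCatalog(group1_names=("G1a", "G1b"))
    cat.add_set("G1a", [gene])
    cat.add_set("G1b", [gene])
    return cat


class TestFrequencyPvalueStandin:
    def test_unmutated_gene_has_p_one(self):
        cohort = [make_record(gene="HOT", pos=i + 1, sample_id=f"S{i}")
                  for i in range(5)]
        p = frequency_pvalue_standin(cohort, {"HOT": 1000, "COLD": 1000})
        assert p["COLD"] == 1.0 and p["HOT"] < 1.0

    def test_concentrated_gene_is_highly_significant(self):
        cohort = []
        k = 0
        for i in range(50):  # 50 of 100 mutations in one of 100 equal genes
            cohort.append(make_record(gene="HOT", pos=i + 1, sample_id=f"S{i % 20}"))
        for j in range(50):
            cohort.append(make_record(gene=f"BG{j}", pos=j + 1, sample_id=f"S{j % 20}"))
        lengths = {"HOT": 1000, **{f"BG{j}": 1000 for j in range(50)},
                   **{f"X{j}": 1000 for j in range(49)}}
        p = frequency_pvalue_standin(cohort, lengths)
        assert p["HOT"] < 1e-10

    def test_gene_missing_from_length_table_warns(self):
        cohort = [make_record(gene="UNKNOWN", sample_id="S1")]
        with pytest.warns(UserWarning, match="length table"):
            p = frequency_pvalue_standin(cohort, {"OTHER": 500})
        assert "UNKNOWN" not in p

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            frequency_pvalue_standin([make_record()], {"TP53": 0})


class TestCombineGenePvalues:
    def test_single_method_gene_flagged_and_passthrough(self):
        df = combine_gene_pvalues({"A": 0.01, "B": 0.02}, {"A": 0.03})
        row = df.set_index("gene")
        assert bool(row.loc["B", "single_method"]) is True
        assert row.loc["B", "p_combined"] == pytest.approx(
            fisher_combine(0.02, 1.0))
        assert not row.loc["A", "single_method"]
        assert "q_value" in df.columns

    def test_underflowed_pvalue_floored_not_fatal(self):
        df = combine_gene_pvalues({"A": 0.0, "B": 0.5}, {"A": 1e-310, "B": 0.5})
        assert np.isfinite(df["p_combined"]).all()
        assert df.set_index("gene").loc["A", "p_combined"] < 1e-200


class TestAnnotateDruggability:
    def _table(self, rows):
        return DrugGeneTable(pd.DataFrame(rows, columns=["gene", "drug",
                                                         "interaction_type",
                                                         "source"]))

    def test_single_interaction_joined(self):
        ann = annotate_druggability(
            ["KRAS"], self._table([("KRAS", "drugX", "inhibitor", "src")]))
        row = ann.gene_drugs.iloc[0]
        assert row["actionable"] and row["drugs"] == "drugX"

    def test_empty_table_yields_empty_annotations(self):
        ann = annotate_druggability(["KRAS", "TP53"], self._table([]))
        assert not ann.gene_drugs["actionable"].any()

    def test_sample_with_two_actionable_genes_flagged_for_combination(self):
        table = self._table([("KRAS", "d1", "", ""), ("BRAF", "d2", "", "")])
        cohort = [
            make_record(sample_id="S1", gene="KRAS", pos=1),
            make_record(sample_id="S1", gene="BRAF", pos=2),
            make_record(sample_id="S2", gene="KRAS", pos=1),
        ]
        ann = annotate_druggability(["KRAS", "BRAF"], table, cohort=cohort)
        combos = ann.combination_candidates.set_index("sample_id")
        assert bool(combos.loc["S1", "combination_candidate"])
        assert not combos.loc["S2", "combination_candidate"]
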