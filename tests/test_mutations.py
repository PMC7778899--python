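from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drivercall.mutations import (
    call_driver_mutations,
    classify_extreme,
    classify_titv,
    filter_hypermutated,
    reve_percentile,
)
from tests.conftest import make_record


class TestClassifyExtreme:
    @pytest.mark.parametrize("vc", [
        "Nonsense_Mutation", "Nonstop_Mutation", "Splice_Site",
        "Frame_Shift_Del", "Frame_Shift_Ins",
    ])
    def test_lof_classes_are_extreme_without_scores(self, vc):
        vt = "DEL" if vc == "Frame_Shift_Del" else ("INS" if vc == "Frame_Shift_Ins" else "SNP")
        ref, alt = ("CA", "C") if vt != "SNP" else ("C", "T")
        rec = make_record(variant_classification=vc, variant_type=vt, ref=ref, alt=alt)
        assert classify_extreme(rec) is True

    @pytest.mark.parametrize("reve,expected", [(0.50, True), (0.49, False), (1.0, True)])
    def test_missense_reve_boundary_inclusive(self, reve, expected):
        rec = make_record(reve_score=reve)
        assert classify_extreme(rec) is expected

    def test_silent_never_extreme_even_with_high_reve(self):
        rec = make_record(variant_classification="Silent", reve_score=0.99)
        assert classify_extreme(rec) is False

    def test_missense_without_reve_is_not_extreme(self):
        assert classify_extreme(make_record()) is False


def _recurrent(n, score, gene="KRAS", pos=100, reve=None, start=0):
    return [
        make_record(sample_id=f"S{i}", gene=gene, chrom="chr12", pos=pos,
                    ref="C", alt="A", ai_driver_score=score, reve_score=reve)
        for i in range(start, start + n)
    ]


class TestCallDriverMutations:
    def test_recurrent_high_score_missense_is_driver(self):
        calls = call_driver_mutations(
            _recurrent(2, 0.96) + _recurrent(1, 0.97, start=2))
        (call,) = calls
        assert call.is_driver and call.n_patients == 3

    def test_singleton_high_score_is_not_driver(self):
        (call,) = call_driver_mutations(_recurrent(1, 0.99))
        assert not call.is_driver

    def test_recurrent_below_threshold_is_not_driver(self):
        (call,) = call_driver_mutations(_recurrent(3, 0.90))
        assert not call.is_driver

    def test_drivers_are_all_missense(self):
        cohort = _recurrent(3, 0.99) + [
            make_record(sample_id=f"S{i}", gene="TP53", pos=50,
                        variant_classification="Nonsense_Mutation",
                        ai_driver_score=0.99)
            for i in range(3)
        ]
        calls = call_driver_mutations(cohort)
        for c in calls:
            if c.is_driver:
                assert c.variant_classification == "Missense_Mutation"

    def test_row_permutation_and_sample_duplication_invariance(self):
        cohort = _recurrent(2, 0.96) + _recurrent(2, 0.85, gene="EGFR", pos=7)
        base = call_driver_mutations(cohort)
        permuted = call_driver_mutations(cohort[::-1])
        duplicated = call_driver_mutations(cohort + [cohort[0]])
        assert base == permuted == duplicated

    def test_lowering_thresholds_never_shrinks_driver_set(self):
        rng = np.random.default_rng(42)
        cohort = []
        for j in range(30):
            cohort += _recurrent(int(rng.integers(1, 5)),
                                 float(rng.uniform(0.8, 1.0)),
                                 gene=f"G{j}", pos=10 + j)
        def drivers(thr, rec):
            return {c.key for c in call_driver_mutations(cohort, thr, rec) if c.is_driver}
        assert drivers(0.95, 2) <= drivers(0.90, 2)
        assert drivers(0.95, 2) <= drivers(0.95, 1)

    def test_extreme_flags_unchanged_by_ai_scores(self):
        with_ai = _recurrent(2, 0.99, reve=0.7)
        without_ai = [make_record(sample_id=r.sample_id, gene=r.gene,
                                  chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                                  reve_score=r.reve_score)
                      for r in with_ai]
        a = [c.is_extreme for c in call_driver_mutations(with_ai)]
        b = [c.is_extreme for c in call_driver_mutations(without_ai)]
        assert a == b == [True]


class TestRevePercentile:
    def test_hand_computed_examples(self):
        np.testing.assert_allclose(reve_percentile([0.1, 0.5, 0.9]), [1/3, 2/3, 1.0])
        np.testing.assert_allclose(reve_percentile([0.4, 0.4]), [0.5, 0.5])
        np.testing.assert_allclose(reve_percentile([0.7]), [1.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reve_percentile([])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_order_preserving_and_bounded(self, scores):
        pct = reve_percentile(scores)
        assert np.all(pct > 0) and np.all(pct <= 1)
        order = np.argsort(scores, kind="stable")
        assert np.all(np.diff(pct[order]) >= 0)
        if len(set(scores)) == len(scores):
            assert pct[int(np.argmax(scores))] == 1.0


class TestClassifyTitv:
    @pytest.mark.parametrize("ref,alt,conv,ti", [
        ("C", "T", "C>T", True),
        ("G", "A", "C>T", True),   # purine reference collapsed
        ("C", "A", "C>A", False),
        ("T", "C", "T>C", True),
        ("A", "C", "T>G", False),  # A>C complements to T>G
        ("G", "T", "C>A", False),
    ])
    def test_conversion_classes(self, ref, alt, conv, ti):
        rec = make_record(ref=ref, alt=alt)
        got = classify_titv(rec)
        assert got.conversion == conv and got.is_transition is ti

    def test_all_twelve_substitutions_collapse_to_six_classes(self):
        convs = set()
        for ref in "ACGT":
            for alt in "ACGT":
                if ref != alt:
                    convs.add(classify_titv(make_record(ref=ref, alt=alt)).conversion)
        assert convs == {"C>A", "C>G", "C>T", "T>A", "T>C", "T>G"}

    def test_non_snp_rejected(self):
        rec = make_record(variant_type="DEL", ref="CA", alt="C",
                          variant_classification="Frame_Shift_Del")
        with pytest.raises(ValueError):
            classify_titv(rec)


class TestFilterHypermutated:
    def _cohort(self, counts):
        recs = []
        for s, n in counts.items():
            recs += [make_record(sample_id=s, pos=i + 1) for i in range(n)]
        return recs

    def test_heavy_sample_removed(self):
        kept, removed = filter_hypermutated(
            self._cohort({"A": 10, "B": 10, "C": 5000}), 1000)
        assert removed == ["C"] and len(kept) == 20

    def test_generous_threshold_removes_nothing(self):
        cohort = self._cohort({"A": 3, "B": 5})
        kept, removed = filter_hypermutated(cohort, 100)
        assert removed == [] and kept == cohort

    def test_boundary_is_strictly_greater(self):
        kept, removed = filter_hypermutated(self._cohort({"A": 3, "B": 3, "C": 3}), 3)
        assert removed == [] and len(kept) == 9
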