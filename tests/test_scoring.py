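"""Weighted overlap, confidence, independence, scaling, imputation, reliability."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from iddi.datasets import canonical_pair
from iddi.scoring import (
    DatasetConfidence,
    EvidenceRecord,
    ScoringError,
    WoMatrix,
    confidence_score,
    impute_scoreless,
    independence_score,
    reliability_score,
    restricted_subset,
    scale_prediction_scores,
    weighted_overlap,
    wo_matrix,
)

from _util import make_ds, wo_brute

A = make_ds("a", [("D1", "D2"), ("D1", "D3"), ("D4", "D5")])
B = make_ds("b", [("D1", "D2"), ("D2", "D3")])


class TestWeightedOverlap:
    def test_restricted_subset_example(self):
        got = restricted_subset(A, B)
        assert {(p.a, p.b) for p in got} == {("D1", "D2"), ("D1", "D3")}

    def test_restricted_subset_disjoint_universes(self):
        c = make_ds("c", [("X1", "X2")])
        assert restricted_subset(A, c) == set()

    def test_restricted_subset_self_identity(self):
        assert restricted_subset(A, A) == A.ddis

    def test_worked_example(self):
        # |Ia ∩ Ib| = 1, |Ia→b| = |Ib→a| = 2
        assert weighted_overlap(A, B) == pytest.approx(0.5)

    def test_self_overlap_is_one(self):
        assert weighted_overlap(A, A) == 1.0

    def test_disjoint_universes_zero_denominator(self):
        c = make_ds("c", [("X1", "X2")])
        assert weighted_overlap(A, c) == 0.0

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = random.Random(7)
        domains = [f"D{i}" for i in range(12)]
        for _ in range(200):
            pa = {tuple(sorted(rng.sample(domains, 2))) for _ in range(rng.randint(1, 30))}
            pb = {tuple(sorted(rng.sample(domains, 2))) for _ in range(rng.randint(1, 30))}
            a, b = make_ds("a", pa), make_ds("b", pb)
            got = weighted_overlap(a, b)
            assert got == pytest.approx(wo_brute(pa, pb))
            assert got == pytest.approx(weighted_overlap(b, a))  # symmetry
            assert 0.0 <= got <= 1.0

    def test_wo_matrix_diagonal_and_symmetry(self):
        m = wo_matrix([A, B])
        assert m.get("a", "a") == 1.0 and m.get("b", "b") == 1.0
        assert m.get("a", "b") == m.get("b", "a") == pytest.approx(0.5)


class TestConfidence:
    def test_identical_to_gsp_is_one(self):
        assert confidence_score(B, set(B.ddis)) == 1.0

    def test_empty_intersection_is_zero(self):
        d = make_ds("d", [("D1", "D2")])
        gsp = {canonical_pair("D1", "D3"), canonical_pair("D2", "D3")}
        assert confidence_score(d, gsp) == 0.0

    def test_empty_gsp_rejected(self):
        with pytest.raises(ScoringError, match="empty"):
            confidence_score(B, set())


def _wo(names, **pairs):
    scores = {(n, n): 1.0 for n in names}
    for key, v in pairs.items():
        a, b = key.split("_")
        scores[(a, b) if a <= b else (b, a)] = v
    return WoMatrix(names=list(names), scores=scores)


class TestIndependence:
    def test_unique_ddi_scores_one(self):
        m = _wo(["d"])
        assert independence_score("d", {"d"}, m) == 1.0

    def test_two_supporters(self):
        m = _wo(["d", "e"], d_e=0.5)
        assert independence_score("d", {"d", "e"}, m) == pytest.approx(1 / 1.5)

    def test_three_fully_overlapping_supporters(self):
        m = _wo(["d", "e", "f"], d_e=1.0, d_f=1.0, e_f=1.0)
        assert independence_score("d", {"d", "e", "f"}, m) == pytest.approx(1 / 3)

    def test_requires_membership(self):
        m = _wo(["d", "e"], d_e=0.5)
        with pytest.raises(ScoringError):
            independence_score("d", {"e"}, m)

    def test_matches_direct_summation_on_random_supporter_sets(self):
        rng = random.Random(3)
        names = [f"ds{i}" for i in range(6)]
        scores = {(n, n): 1.0 for n in names}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                scores[(a, b)] = rng.random()
        m = WoMatrix(names=names, scores=scores)
        for _ in range(100):
            supp = set(rng.sample(names, rng.randint(1, 6)))
            d = rng.choice(sorted(supp))
            expected = 1.0 / (1.0 + sum(
                scores[tuple(sorted((d, e)))] for e in supp if e != d
            ))
            assert independence_score(d, supp, m) == pytest.approx(expected)

    def test_weakly_decreasing_in_supporters(self):
        m = _wo(["d", "e", "f"], d_e=0.4, d_f=0.0, e_f=0.2)
        one = independence_score("d", {"d"}, m)
        two = independence_score("d", {"d", "e"}, m)
        three = independence_score("d", {"d", "e", "f"}, m)
        assert one >= two >= three
        assert three == two  # Wo(d,f)=0 adds nothing


class TestOrdinalScaling:
    def test_three_scores(self):
        ds = make_ds("x", [("A", "B"), ("C", "D"), ("E", "F")], scores=[5, 2, 9])
        got = scale_prediction_scores(ds)
        assert got[canonical_pair("C", "D")] == 0.0
        assert got[canonical_pair("A", "B")] == 0.5
        assert got[canonical_pair("E", "F")] == 1.0

    def test_lower_is_better_inverts(self):
        ds = make_ds("x", [("A", "B"), ("C", "D")], scores=[0.01, 0.5], direction="lower")
        got = scale_prediction_scores(ds)
        assert got[canonical_pair("A", "B")] == 1.0
        assert got[canonical_pair("C", "D")] == 0.0

    def test_ties_get_mean_rank(self):
        ds = make_ds("x", [("A", "B"), ("C", "D")], scores=[3, 3])
        got = scale_prediction_scores(ds)
        assert set(got.values()) == {0.5}

    def test_single_scored_ddi_maps_to_one(self):
        ds = make_ds("x", [("A", "B")], scores=[42.0])
        assert scale_prediction_scores(ds) == {canonical_pair("A", "B"): 1.0}

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=15, unique=True))
    def test_invariant_under_monotone_transform(self, raws):
        pairs = [(f"A{i}", f"B{i}") for i in range(len(raws))]
        ds1 = make_ds("x", pairs, scores=raws)
        ds2 = make_ds("x", pairs, scores=[2.0 * r**3 + r for r in raws])  # strictly monotone
        assert scale_prediction_scores(ds1) == scale_prediction_scores(ds2)
        assert all(0.0 <= v <= 1.0 for v in scale_prediction_scores(ds1).values())


def _rec(dataset, a, b, p=None, ind=1.0):
    return EvidenceRecord(dataset=dataset, ddi=canonical_pair(a, b),
                          scaled_score=p, independence=ind)


class TestImputation:
    def test_bin_mean(self):
        # DDI (A,B) has 2 supporters; scored DDIs with 2 supporters score 0.2 and 0.8
        evidence = [
            _rec("s1", "A", "B", 0.2), _rec("s2", "A", "B", 0.8),
            _rec("s1", "C", "D", 0.9),
            _rec("nos", "E", "F"), _rec("s2", "E", "F", 0.4),
        ]
        impute_scoreless(evidence, {"nos"})
        target = next(r for r in evidence if r.dataset == "nos")
        # (E,F) has 2 supporters; scored evidence in the 2-supporter bin: 0.2, 0.8, 0.4
        assert target.scaled_score == pytest.approx((0.2 + 0.8 + 0.4) / 3)
        assert target.imputed

    def test_empty_bin_falls_back_to_global_mean(self):
        evidence = [
            _rec("s1", "A", "B", 0.4),
            _rec("s1", "C", "D", 0.6),
            _rec("nos", "E", "F"),  # 1-supporter bin holds only scored 0.4, 0.6... not empty
            _rec("nos", "G", "H"),
        ]
        # make the bin for k=2 empty: give (E,F) a second scoreless supporter
        evidence.append(_rec("nos2", "E", "F"))
        impute_scoreless(evidence, {"nos", "nos2"})
        ef = [r for r in evidence if r.ddi == canonical_pair("E", "F")]
        assert all(r.scaled_score == pytest.approx(0.5) for r in ef)  # global mean

    def test_all_scored_is_noop(self):
        evidence = [_rec("s1", "A", "B", 0.3)]
        impute_scoreless(evidence, set())
        assert evidence[0].scaled_score == 0.3 and not evidence[0].imputed

    def test_no_scored_evidence_errors(self):
        with pytest.raises(ScoringError, match="imputation impossible"):
            impute_scoreless([_rec("nos", "A", "B")], {"nos"})


class TestReliability:
    def test_single_supporter(self):
        conf = DatasetConfidence({"d": 0.6})
        r = reliability_score([_rec("d", "A", "B", p=0.8, ind=1.0)], conf)
        assert r == pytest.approx(0.48)

    def test_two_supporters_full_formula(self):
        conf = DatasetConfidence({"d": 0.6, "e": 0.2})
        recs = [_rec("d", "A", "B", p=0.8, ind=0.8), _rec("e", "A", "B", p=0.5, ind=0.8)]
        assert reliability_score(recs, conf) == pytest.approx(0.464)

    def test_zero_prediction_score_contributes_nothing(self):
        conf = DatasetConfidence({"d": 0.6, "e": 0.9})
        recs = [_rec("d", "A", "B", p=0.0, ind=1.0), _rec("e", "A", "B", p=0.5, ind=1.0)]
        assert reliability_score(recs, conf) == pytest.approx(0.45)

    def test_missing_confidence_errors(self):
        with pytest.raises(ScoringError, match="confidence"):
            reliability_score([_rec("d", "A", "B", p=0.5)], DatasetConfidence({}))

    def test_sum_dominates_each_term(self):
        conf = DatasetConfidence({"d": 0.6, "e": 0.2})
        recs = [_rec("d", "A", "B", p=0.8, ind=0.8), _rec("e", "A", "B", p=0.5, ind=0.8)]
        total = reliability_score(recs, conf)
        for rec in recs:
            assert total >= reliability_score([rec], conf)
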