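import itertools
import math

import numpy as np
import pytest

from splicenet.ddi import (
    assign_confidence,
    build_resource_index,
    calibrate_threshold,
    combined_score,
    random_weight_search,
    resource_pair_score,
    score_all_candidates,
)
from splicenet.model import DDIScoreRecord, DomainOccurrence, PPIEdgeRecord, canonical_pair


def occ(protein, domain):
    return DomainOccurrence(protein_id=protein, transcript_id=f"t_{protein}",
                            domain_id=domain, aa_start=1, aa_end=10)


def edges_of(pairs, resource="r1"):
    return [PPIEdgeRecord(a, b, resource) for a, b in pairs]


class TestBuildResourceIndex:
    def test_single_edge_counts(self):
        ix = build_resource_index(edges_of([("p1", "q1")]),
                                  [occ("p1", "A"), occ("q1", "B")])
        assert ix.pair_counts == {("A", "B"): 1}
        assert ix.domain_counts == {"A": 1, "B": 1}

    def test_two_edges_sharing_domain(self):
        # hand enumeration: edges (p1,q1), (p1,q2); dom(p1)={A}, dom(q1)=dom(q2)={B}
        ix = build_resource_index(
            edges_of([("p1", "q1"), ("p1", "q2")]),
            [occ("p1", "A"), occ("q1", "B"), occ("q2", "B")],
        )
        assert ix.pair_counts[("A", "B")] == 2
        assert ix.domain_counts == {"A": 2, "B": 2}

    def test_homodimer_counts_self_pair_once(self):
        ix = build_resource_index(edges_of([("p1", "p1")]), [occ("p1", "A")])
        assert ix.pair_counts == {("A", "A"): 1}
        assert ix.domain_counts == {"A": 1}

    def test_homodimer_two_domains(self):
        ix = build_resource_index(edges_of([("p1", "p1")]),
                                  [occ("p1", "A"), occ("p1", "B")])
        assert ix.pair_counts == {("A", "A"): 1, ("A", "B"): 1, ("B", "B"): 1}

    def test_mixed_resources_rejected(self):
        with pytest.raises(ValueError):
            build_resource_index(
                [PPIEdgeRecord("a", "b", "r1"), PPIEdgeRecord("c", "d", "r2")], [])

    def test_m_at_least_n_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            edges, occs = _random_instance(rng)
            ix = build_resource_index(edges, occs)
            for (a, b), n in ix.pair_counts.items():
                assert ix.domain_counts[a] >= n
                assert ix.domain_counts[b] >= n


class TestResourcePairScore:
    def test_formula(self):
        # n=1, m(A)=2, m(B)=1 -> 1/sqrt(2): dom(p1)={A}, dom(q1)={B}, dom(q2)={}
        ix = build_resource_index(
            edges_of([("p1", "q1"), ("p1", "q2")]),
            [occ("p1", "A"), occ("q1", "B")],
        )
        assert resource_pair_score(ix, "A", "B") == pytest.approx(1 / math.sqrt(2))

    def test_never_cooccurring_pair_scores_zero(self):
        ix = build_resource_index(edges_of([("p1", "q1")]),
                                  [occ("p1", "A"), occ("q1", "B")])
        assert resource_pair_score(ix, "A", "Z") == 0.0

    def test_perfect_cooccurrence_scores_one(self):
        ix = build_resource_index(
            edges_of([("p1", "q1"), ("p2", "q2")]),
            [occ("p1", "A"), occ("q1", "B"), occ("p2", "A"), occ("q2", "B")],
        )
        assert resource_pair_score(ix, "A", "B") == 1.0

    def test_symmetric_in_domain_order(self):
        ix = build_resource_index(edges_of([("p1", "q1")]),
                                  [occ("p1", "A"), occ("q1", "B")])
        assert resource_pair_score(ix, "A", "B") == resource_pair_score(ix, "B", "A")


class TestCombinedScore:
    def test_equal_weights_is_arithmetic_mean(self):
        assert combined_score({"r1": 1, "r2": 1}, {"r1": 0.5, "r2": 0.1}) == \
            pytest.approx(0.3)

    def test_uniform_scaling_invariance(self):
        s = {"r1": 0.5, "r2": 0.1}
        assert combined_score({"r1": 3, "r2": 7}, s) == \
            pytest.approx(combined_score({"r1": 30, "r2": 70}, s))

    def test_lopsided_weights(self):
        assert combined_score({"r1": 99, "r2": 1}, {"r1": 1.0, "r2": 0.0}) == \
            pytest.approx(0.99)

    def test_missing_resource_contributes_zero(self):
        assert combined_score({"r1": 1, "r2": 1}, {"r1": 1.0}) == pytest.approx(0.5)

    def test_empty_weights_error(self):
        with pytest.raises(ValueError):
            combined_score({}, {})


def _random_instance(rng, n_proteins=12, n_domains=6, n_edges=15):
    proteins = [f"p{i}" for i in range(n_proteins)]
    occs = []
    for p in proteins:
        for d in rng.choice(n_domains, size=rng.integers(1, 3), replace=False):
            occs.append(occ(p, f"d{d}"))
    pairs = set()
    while len(pairs) < n_edges:
        i, j = rng.integers(0, n_proteins, size=2)
        pairs.add(canonical_pair(proteins[int(i)], proteins[int(j)]))
    return edges_of(sorted(pairs)), occs


def _brute_force_counts(edges, occs):
    """Independent double-loop recount of n(a,b) and m(d)."""
    dom = {}
    for o in occs:
        dom.setdefault(o.protein_id, set()).add(o.domain_id)
    domains = sorted({o.domain_id for o in occs})
    n = {}
    m = {}
    for a, b in itertools.combinations_with_replacement(domains, 2):
        count = 0
        for e in edges:
            da, db = dom.get(e.protein_a, set()), dom.get(e.protein_b, set())
            if (a in da and b in db) or (b in da and a in db):
                count += 1
        if count:
            n[(a, b)] = count
    for d in domains:
        count = sum(1 for e in edges
                    if d in dom.get(e.protein_a, set()) | dom.get(e.protein_b, set()))
        if count:
            m[d] = count
    return n, m


class TestScoreAllCandidates:
    def test_against_bruteforce_double_loop(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            edges, occs = _random_instance(rng)
            ix = build_resource_index(edges, occs)
            n, m = _brute_force_counts(edges, occs)
            assert ix.pair_counts == n
            assert ix.domain_counts == m
            for rec in score_all_candidates([ix]):
                expected = n[rec.key] / math.sqrt(m[rec.domain_a] * m[rec.domain_b])
                assert rec.combined == pytest.approx(expected)
                assert 0.0 < rec.combined <= 1.0

    def test_supporting_resource_count(self):
        occs = [occ("p1", "A"), occ("q1", "B")]
        ix1 = build_resource_index(edges_of([("p1", "q1")], "r1"), occs)
        ix2 = build_resource_index(edges_of([("p1", "q1")], "r2"), occs)
        ix3 = build_resource_index(edges_of([("x", "y")], "r3"), occs)
        (rec,) = score_all_candidates([ix1, ix2, ix3])
        assert rec.n_supporting_resources == 2

    def test_symmetric_under_endpoint_swap(self):
        occs = [occ("p1", "A"), occ("q1", "B"), occ("q2", "B")]
        ix_fwd = build_resource_index(edges_of([("p1", "q1"), ("p1", "q2")]), occs)
        ix_rev = build_resource_index(edges_of([("q1", "p1"), ("q2", "p1")]), occs)
        assert score_all_candidates([ix_fwd]) == score_all_candidates([ix_rev])

    def test_adding_supporting_ppi_never_decreases_score(self):
        # enumerated small case: adding an (A, B) edge grows n at least as
        # fast as sqrt(m_a * m_b)
        occs = [occ("p1", "A"), occ("q1", "B"), occ("p2", "A"), occ("q2", "B")]
        base = edges_of([("p1", "q1")])
        grown = edges_of([("p1", "q1"), ("p2", "q2")])
        s0 = resource_pair_score(build_resource_index(base, occs), "A", "B")
        s1 = resource_pair_score(build_resource_index(grown, occs), "A", "B")
        assert s1 >= s0


def _records(scored):
    return [
        DDIScoreRecord(domain_a=a, domain_b=b, per_resource={"r1": s}, combined=s,
                       n_supporting_resources=1)
        for (a, b), s in scored.items()
    ]


class TestCalibrateThreshold:
    def test_three_record_example(self):
        # derived by enumerating all 3 candidate thresholds:
        #   t=0.9: P=1, R=1/2, F1=2/3; t=0.8: P=1, R=1, F1=1; t=0.2: P=2/3, R=1, F1=0.8
        recs = _records({("A", "B"): 0.9, ("C", "D"): 0.8, ("E", "F"): 0.2})
        cal = calibrate_threshold(recs, {("A", "B"), ("C", "D")})
        assert cal.threshold == pytest.approx(0.8)
        assert cal.f1 == pytest.approx(1.0)

    def test_all_true_picks_min_score(self):
        recs = _records({("A", "B"): 0.9, ("C", "D"): 0.3})
        cal = calibrate_threshold(recs, {("A", "B"), ("C", "D")})
        assert cal.threshold == pytest.approx(0.3)
        assert cal.f1 == pytest.approx(1.0)

    def test_disjoint_truth_errors(self):
        recs = _records({("A", "B"): 0.9})
        with pytest.raises(ValueError, match="uncalibratable"):
            calibrate_threshold(recs, {("X", "Y")})

    def test_returned_f1_maximal_over_curve(self):
        rng = np.random.default_rng(3)
        scores = {(f"a{i}", f"b{i}"): float(rng.random()) for i in range(30)}
        truth = {k for k in scores if rng.random() < 0.4}
        if not truth:
            truth = {next(iter(scores))}
        cal = calibrate_threshold(_records(scores), truth)
        assert cal.curve
        assert all(cal.f1 >= f1 for _t, _p, _r, f1 in cal.curve)

    def test_unscored_truth_convention_flag(self):
        recs = _records({("A", "B"): 0.9})
        lenient = calibrate_threshold(recs, {("A", "B"), ("X", "Y")})
        strict = calibrate_threshold(recs, {("A", "B"), ("X", "Y")},
                                     count_unscored_truth=True)
        assert lenient.recall == pytest.approx(1.0)
        assert strict.recall == pytest.approx(0.5)


class TestAssignConfidence:
    @pytest.mark.parametrize("score,n_res,expected", [
        (0.9, 3, "gold"),
        (0.6, 1, "silver"),
        (0.3, 1, "bronze"),
        (0.2, 2, "below"),
    ])
    def test_tier_rules(self, score, n_res, expected):
        rec = DDIScoreRecord("A", "B", {}, score, n_res)
        assign_confidence([rec], threshold=0.5)
        assert rec.tier == expected


class TestRandomWeightSearch:
    def _single_resource(self):
        occs = [occ("p1", "A"), occ("q1", "B"), occ("p2", "C"), occ("q2", "D")]
        return build_resource_index(
            edges_of([("p1", "q1"), ("p2", "q2")]), occs)

    def test_single_resource_f1_invariant_across_draws(self):
        ix = self._single_resource()
        _w, _cal, history = random_weight_search(
            [ix], {("A", "B")}, n_iter=200, seed=11)
        f1s = {round(f1, 12) for _weights, f1 in history}
        assert len(f1s) == 1

    def test_same_seed_reproduces_best_vector(self):
        ix = self._single_resource()
        w1, c1, _ = random_weight_search([ix], {("A", "B")}, n_iter=50, seed=4)
        w2, c2, _ = random_weight_search([ix], {("A", "B")}, n_iter=50, seed=4)
        assert w1 == w2 and c1 == c2

    def test_matches_exhaustive_search_on_two_resource_toy(self):
        # resource r1 alone separates truth perfectly; r2 is pure noise
        occs = [occ("p1", "A"), occ("q1", "B"), occ("p2", "C"), occ("q2", "D")]
        r1 = build_resource_index(edges_of([("p1", "q1")], "r1"), occs)
        r2 = build_resource_index(edges_of([("p2", "q2")], "r2"), occs)
        truth = {("A", "B")}

        best_exhaustive = 0.0
        for w1, w2 in itertools.product(range(1, 4), repeat=2):
            recs = score_all_candidates([r1, r2], {"r1": w1, "r2": w2})
            best_exhaustive = max(best_exhaustive,
                                  calibrate_threshold(recs, truth).f1)
        _w, cal, _ = random_weight_search([r1, r2], truth, n_iter=100,
                                          weight_min=1, weight_max=3, seed=0)
        assert cal.f1 == pytest.approx(best_exhaustive)
        # equal weights cannot beat the best found vector
        equal = calibrate_threshold(score_all_candidates([r1, r2]), truth)
        assert cal.f1 >= equal.f1

    def test_n_iter_validation(self):
        with pytest.raises(ValueError):
            random_weight_search([self._single_resource()], {("A", "B")}, n_iter=0)
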