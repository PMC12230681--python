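import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_transcript
from oracles import (
    aa_interval_by_enumeration,
    brute_force_affected_edges,
    footprint_by_enumeration,
    random_affected_features,
    random_annotated_network,
)
from splicenet.mapping import (
    compute_domain_footprints,
    derive_affected_edges,
    filter_events,
    genomic_to_protein,
    map_event_to_features,
    protein_to_genomic,
    summarize_affected_features,
)
from splicenet.model import DomainOccurrence, SpliceEvent, TranscriptModel


def event(gene="gX", start=1, end=10, dpsi=0.2, sig=0.01, chrom="chr1", strand="+"):
    return SpliceEvent(gene, chrom, strand, start, end, dpsi, sig, "generic_bed")


class TestFilterEvents:
    def test_passing_event_kept(self):
        assert filter_events([event(dpsi=0.2, sig=0.01)], 0.1, 0.05)

    def test_negative_delta_psi_kept(self):
        evs = filter_events([event(dpsi=-0.2, sig=0.01)], 0.1, 0.05)
        assert evs and evs[0].delta_psi == -0.2

    def test_boundaries_inclusive(self):
        assert filter_events([event(dpsi=0.1, sig=0.05)], 0.1, 0.05)

    def test_subthreshold_dropped(self):
        assert not filter_events([event(dpsi=0.04, sig=0.01)], 0.05, 0.05)
        assert not filter_events([event(dpsi=0.2, sig=0.06)], 0.05, 0.05)

    @given(dpsi=st.floats(-1, 1), sig=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_kept_iff_both_conditions(self, dpsi, sig):
        kept = bool(filter_events([event(dpsi=dpsi, sig=sig)], 0.05, 0.05))
        assert kept == (abs(dpsi) >= 0.05 and sig <= 0.05)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            filter_events([], dpsi_min=1.5, p_max=0.05)


class TestProteinToGenomic:
    def test_first_two_codons_plus_strand(self, plus_transcript):
        # coding positions 1-6 are genomic 101-106
        assert protein_to_genomic(plus_transcript, 1, 2) == ((101, 106),)

    def test_junction_spanning_codons(self, plus_transcript):
        # aa 20-21 -> coding nts 58-63 -> (158,160) + (201,203)
        assert protein_to_genomic(plus_transcript, 20, 21) == ((158, 160), (201, 203))

    def test_first_codon_minus_strand(self, minus_transcript):
        assert protein_to_genomic(minus_transcript, 1, 1) == ((228, 230),)

    def test_beyond_protein_length_errors(self, plus_transcript):
        with pytest.raises(ValueError, match="beyond protein length"):
            protein_to_genomic(plus_transcript, 1, 31)

    def test_no_cds_errors(self):
        tm = TranscriptModel("t", "g", "chr1", "+", exons=((1, 30),))
        with pytest.raises(ValueError, match="no CDS"):
            protein_to_genomic(tm, 1, 1)

    def test_matches_enumeration_oracle(self, plus_transcript, minus_transcript):
        for tm in (plus_transcript, minus_transcript):
            for aa_start in range(1, 31):
                for aa_end in range(aa_start, 31):
                    assert protein_to_genomic(tm, aa_start, aa_end) == \
                        footprint_by_enumeration(tm, aa_start, aa_end)

    def test_footprint_length_is_three_times_span(self, plus_transcript):
        for a, b in [(1, 1), (5, 10), (19, 22), (1, 30)]:
            fp = protein_to_genomic(plus_transcript, a, b)
            assert sum(e - s + 1 for s, e in fp) == 3 * (b - a + 1)

    def test_consecutive_intervals_additive(self, minus_transcript):
        fp_left = protein_to_genomic(minus_transcript, 1, 10)
        fp_right = protein_to_genomic(minus_transcript, 11, 30)
        merged = protein_to_genomic(minus_transcript, 1, 30)
        pos = set()
        for s, e in fp_left + fp_right:
            chunk = set(range(s, e + 1))
            assert not chunk & pos  # disjoint
            pos |= chunk
        assert pos == {p for s, e in merged for p in range(s, e + 1)}


class TestGenomicToProtein:
    def test_round_trip_identity(self, plus_transcript, minus_transcript):
        for tm in (plus_transcript, minus_transcript):
            for fp in [protein_to_genomic(tm, 5, 10)]:
                lo = min(s for s, _ in fp)
                hi = max(e for _, e in fp)
                assert genomic_to_protein(tm, (lo, hi)) == (5, 10)

    def test_intronic_interval_returns_none(self, plus_transcript):
        assert genomic_to_protein(plus_transcript, (161, 200)) is None

    def test_single_nucleotide_of_codon_seven(self, plus_transcript):
        # codon 7 covers genomic 119-121; one overlapping nt -> (7, 7)
        assert genomic_to_protein(plus_transcript, (121, 121)) == (7, 7)

    def test_matches_enumeration_oracle(self, plus_transcript, minus_transcript):
        rng = np.random.default_rng(0)
        for tm in (plus_transcript, minus_transcript):
            for _ in range(200):
                g1 = int(rng.integers(90, 240))
                g2 = g1 + int(rng.integers(0, 60))
                assert genomic_to_protein(tm, (g1, g2)) == \
                    aa_interval_by_enumeration(tm, g1, g2)

    def test_randomized_round_trip_both_strands(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            tm = random_transcript(rng)
            n_aa = tm.protein_length
            a = int(rng.integers(1, n_aa + 1))
            b = int(rng.integers(a, n_aa + 1))
            fp = protein_to_genomic(tm, a, b)
            assert sum(e - s + 1 for s, e in fp) == 3 * (b - a + 1)
            lo, hi = min(s for s, _ in fp), max(e for _, e in fp)
            assert genomic_to_protein(tm, (lo, hi)) == (a, b)


class TestComputeDomainFootprints:
    def test_footprint_attached(self, plus_transcript):
        occ = DomainOccurrence("pX", "t_plus", "PF1", 1, 2)
        (out,) = compute_domain_footprints([occ], [plus_transcript])
        assert out.genomic_footprint == ((101, 106),)

    def test_unliftable_left_empty_with_warning(self, caplog):
        tm = TranscriptModel("t7", "g", "chr1", "+", exons=((1, 31),), cds=((1, 31),),
                            protein_id="p")  # CDS length 31, not divisible by 3
        occ = DomainOccurrence("p", "t7", "PF1", 1, 2)
        with caplog.at_level("WARNING"):
            (out,) = compute_domain_footprints([occ], [tm])
        assert out.genomic_footprint == ()


class TestMapEventToFeatures:
    @pytest.fixture
    def setup(self, plus_transcript):
        occ = DomainOccurrence("pX", "t_plus", "PF1", 1, 20)  # footprint (101,160)
        (occ,) = compute_domain_footprints([occ], [plus_transcript])
        return plus_transcript, occ

    def test_overlapping_exon_affects_domain(self, setup):
        tm, occ = setup
        feats = map_event_to_features(event(start=150, end=160), [tm], [occ])
        assert [(o.domain_id, nt) for o, nt in feats.domains] == [("PF1", 11)]

    def test_adjacent_interval_does_not_affect(self, setup):
        tm, occ = setup
        feats = map_event_to_features(event(start=161, end=200), [tm], [occ])
        assert feats.is_empty

    def test_event_in_footprint_gap_not_affected(self):
        # extra non-coding exon (170,180) sits between the two CDS segments
        tm = TranscriptModel("t3", "gX", "chr1", "+",
                             exons=((101, 160), (170, 180), (201, 230)),
                             cds=((101, 160), (201, 230)), protein_id="pX")
        occ = DomainOccurrence("pX", "t3", "PF1", 1, 30)
        (occ,) = compute_domain_footprints([occ], [tm])
        assert occ.genomic_footprint == ((101, 160), (201, 230))
        feats = map_event_to_features(event(start=170, end=180), [tm], [occ])
        assert "t3" in feats.transcripts  # exon overlap, but no feature hit
        assert feats.is_empty

    def test_gene_without_models_marked_unmapped(self, setup):
        tm, occ = setup
        feats = map_event_to_features(event(gene="other"), [tm], [occ])
        assert feats.unmapped

    def test_motif_and_residue_overlap(self, plus_transcript):
        # motif aa 1-5 -> genomic (101,115); residue 4 -> (110,112)
        feats = map_event_to_features(
            event(start=101, end=112), [plus_transcript], [],
            motif_records=[("partner", "PFx", "pX", 1, 5)],
            residue_records=[("pX", (4,), "partner", (9,))],
        )
        assert feats.motifs == [("pX", "t_plus", 1, 5, 12)]
        assert feats.residues == [("pX", "t_plus", 4, 3)]


class TestDeriveAffectedEdges:
    def test_agrees_with_bruteforce_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            network, dom_of = random_annotated_network(rng, max_edges=50)
            features = random_affected_features(rng, network, dom_of)
            got = derive_affected_edges(network, features)
            expected = brute_force_affected_edges(network, features)
            assert {k: (len(l), len(s)) for k, (l, s) in got.edges.items()} == expected

    def test_no_features_yields_empty_set(self):
        rng = np.random.default_rng(1)
        network, _dom = random_annotated_network(rng)
        assert derive_affected_edges(network, []).n == 0

    def test_monotone_in_event_list(self):
        rng = np.random.default_rng(9)
        network, dom_of = random_annotated_network(rng)
        features = random_affected_features(rng, network, dom_of)
        partial = set(derive_affected_edges(network, features[:1]).edges)
        full = set(derive_affected_edges(network, features).edges)
        assert partial <= full


class TestSummarize:
    def _feats(self, gene, domains):
        from splicenet.model import AffectedFeatures
        ev = event(gene=gene)
        f = AffectedFeatures(event=ev)
        for d in domains:
            f.domains.append((DomainOccurrence(f"P_{gene}", f"t_{gene}", d, 1, 5), 10))
        return f

    def test_same_domain_hit_twice_counted_once(self):
        df = summarize_affected_features(
            [self._feats("g1", ["PF1"]), self._feats("g1", ["PF1"])])
        assert df.loc[0, "n_features"] == 1

    def test_empty_input_empty_table(self):
        assert summarize_affected_features([]).empty

    def test_three_domains_two_genes(self):
        df = summarize_affected_features(
            [self._feats("g1", ["PF1", "PF2"]), self._feats("g2", ["PF3"])])
        assert len(df) == 2
        assert df.set_index("gene")["n_features"].to_dict() == {"g1": 2, "g2": 1}
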