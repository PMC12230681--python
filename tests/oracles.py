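"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's own bookkeeping: they re-derive
expected results by exhaustive scans over evidence items, draw subsets, or
coding-position enumeration.
"""

import itertools
from math import comb

import numpy as np

from splicenet.model import (
    AnnotatedEdge,
    DomainOccurrence,
    EvidenceItem,
    JointNetwork,
    SpliceEvent,
)


def hypergeom_upper_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration over all C(N, n) draw subsets."""
    hits = 0
    for subset in itertools.combinations(range(N), n):
        if sum(1 for x in subset if x < K) >= k:
            hits += 1
    return hits / comb(N, n)


def overlap_count_histogram(N: int, K: int, n: int) -> list[int]:
    """#draw subsets by overlap with the first K elements (enumeration)."""
    hist = [0] * (n + 1)
    for subset in itertools.combinations(range(N), n):
        hist[sum(1 for x in subset if x < K)] += 1
    return hist


def bh_stepup(p_values):
    """Literal Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def enumerate_coding_positions(tm) -> list[int]:
    """Genomic positions of coding nucleotides in 5'->3' order, one by one."""
    out = []
    cds = list(tm.cds) if tm.strand == "+" else list(reversed(tm.cds))
    for s, e in cds:
        positions = range(s, e + 1) if tm.strand == "+" else range(e, s - 1, -1)
        out.extend(positions)
    return out


def footprint_by_enumeration(tm, aa_start: int, aa_end: int):
    """Footprint as maximal ascending runs, via per-nucleotide enumeration."""
    coding = enumerate_coding_positions(tm)
    positions = sorted(coding[3 * (aa_start - 1):3 * aa_end])
    runs = []
    for pos in positions:
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    return tuple(runs)


def aa_interval_by_enumeration(tm, g1: int, g2: int):
    """Minimal aa interval covering the CDS overlap, via enumeration."""
    coding = enumerate_coding_positions(tm)
    offsets = [i + 1 for i, pos in enumerate(coding) if g1 <= pos <= g2]
    if not offsets:
        return None
    return ((min(offsets) + 2) // 3, (max(offsets) + 2) // 3)


# ---------------------------------------------------------------------------
# Random annotated networks and the per-evidence-item scan


def random_annotated_network(rng: np.random.Generator, max_edges: int = 50):
    """A random JointNetwork with DDI/DMI/residue evidence on each edge."""
    n_proteins = int(rng.integers(4, 12))
    proteins = [f"p{i:02d}" for i in range(n_proteins)]
    domains = [f"d{i}" for i in range(8)]
    dom_of = {p: sorted(rng.choice(domains, size=int(rng.integers(1, 4)),
                                   replace=False).tolist())
              for p in proteins}
    edges = {}
    n_edges = int(rng.integers(1, max_edges + 1))
    for _ in range(n_edges):
        i, j = sorted(rng.integers(0, n_proteins, size=2))
        key = (proteins[int(i)], proteins[int(j)])
        if key in edges:
            continue
        items = []
        for _k in range(int(rng.integers(1, 4))):
            kind = rng.choice(["ddi", "dmi", "residue"])
            if kind == "ddi":
                da = dom_of[key[0]][int(rng.integers(0, len(dom_of[key[0]])))]
                db = dom_of[key[1]][int(rng.integers(0, len(dom_of[key[1]])))]
                items.append(EvidenceItem(kind="ddi_experimental",
                                          domain_a=da, domain_b=db))
            elif kind == "dmi":
                on_a = bool(rng.integers(0, 2))
                host = key[0] if on_a else key[1]
                dom = dom_of[host][int(rng.integers(0, len(dom_of[host])))]
                start = int(rng.integers(1, 50))
                items.append(EvidenceItem(kind="dmi", domain_a=dom,
                                          motif_span=(start, start + 5),
                                          domain_on_a=on_a))
            else:
                items.append(EvidenceItem(
                    kind="residue",
                    residue_positions_a=tuple(sorted(
                        int(x) for x in rng.integers(1, 60, size=2))),
                    residue_positions_b=(int(rng.integers(1, 60)),),
                ))
        edges[key] = AnnotatedEdge(key[0], key[1], tuple(items))
    transcript_to_protein = {f"t_{p}": p for p in proteins}
    return JointNetwork(
        proteins=set(proteins), edges=edges, unannotated_edges=set(),
        domains_by_protein={p: frozenset(d) for p, d in dom_of.items()},
        transcript_to_protein=transcript_to_protein, provenance={},
    ), dom_of


def random_affected_features(rng, network, dom_of):
    """Random affected-feature sets expressed as AffectedFeatures objects."""
    from splicenet.model import AffectedFeatures

    proteins = sorted(network.proteins)
    features = []
    for i in range(int(rng.integers(1, 5))):
        event = SpliceEvent(f"g{i}", "chr1", "+", 100 * i + 1, 100 * i + 50,
                            0.2, 0.001, "generic_bed")
        feats = AffectedFeatures(event=event)
        for p in proteins:
            if rng.random() < 0.3 and dom_of[p]:
                dom = dom_of[p][int(rng.integers(0, len(dom_of[p])))]
                feats.domains.append((DomainOccurrence(
                    protein_id=p, transcript_id=f"t_{p}", domain_id=dom,
                    aa_start=1, aa_end=10), 30))
            if rng.random() < 0.15:
                start = int(rng.integers(1, 50))
                feats.motifs.append((p, f"t_{p}", start, start + 5, 6))
            if rng.random() < 0.15:
                feats.residues.append((p, f"t_{p}", int(rng.integers(1, 60)), 3))
        features.append(feats)
    return features


def evidence_item_lost(item, key, affected_domains, affected_motifs,
                       affected_residues) -> bool:
    """Single-item loss rule, written out independently of the package."""
    pa, pb = key
    if item.kind in ("ddi_experimental", "ddi_predicted"):
        return (pa, item.domain_a) in affected_domains or \
            (pb, item.domain_b) in affected_domains
    if item.kind == "dmi":
        dom_host, motif_host = (pa, pb) if item.domain_on_a else (pb, pa)
        if (dom_host, item.domain_a) in affected_domains:
            return True
        return (motif_host, item.motif_span[0], item.motif_span[1]) in affected_motifs
    for prot, positions in ((pa, item.residue_positions_a),
                            (pb, item.residue_positions_b)):
        for pos in positions:
            if (prot, pos) in affected_residues:
                return True
    return False


def brute_force_affected_edges(network, features):
    """Expected affected-edge map via a per-evidence-item scan."""
    affected_domains = set()
    affected_motifs = set()
    affected_residues = set()
    for feats in features:
        for occ, _nt in feats.domains:
            affected_domains.add((occ.protein_id, occ.domain_id))
        for prot, _tid, ms, me, _nt in feats.motifs:
            affected_motifs.add((prot, ms, me))
        for prot, _tid, pos, _nt in feats.residues:
            affected_residues.add((prot, pos))
    expected = {}
    for key, edge in network.edges.items():
        lost = [it for it in edge.evidence
                if evidence_item_lost(it, key, affected_domains, affected_motifs,
                                      affected_residues)]
        if lost:
            expected[key] = (len(lost), len(edge.evidence) - len(lost))
    return expected
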