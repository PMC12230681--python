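"""Joint PPI/DDI network construction and on-the-fly characteristics.

PPI edges are annotated with every piece of domain-level evidence that can
mediate them: experimental DDI templates, predicted DDIs passing the tier
filter, DMIs, and residue-level records. Edges with no attaching evidence
are retained separately so nothing is silently dropped.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from itertools import combinations_with_replacement, product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model import (
    AnnotatedEdge,
    DDI_EXPERIMENTAL,
    DDI_PREDICTED,
    DMI,
    DomainOccurrence,
    EvidenceItem,
    JointNetwork,
    NetworkStats,
    PathwayGeneSet,
    PPIEdgeRecord,
    RESIDUE,
    TIERS,
    canonical_pair,
)

logger = logging.getLogger(__name__)

__all__ = ["build_joint_network", "isoform_view", "network_characteristics",
           "export_network_json", "export_edge_evidence_tsv"]


def _normalize_tier_filter(tier_filter: Iterable[str] | None) -> frozenset[str]:
    tiers = frozenset(tier_filter or ())
    unknown = tiers - set(TIERS)
    if unknown:
        raise ValueError(f"unknown tiers {sorted(unknown)}; expected subset of {TIERS}")
    return tiers


def build_joint_network(
    ppi_edges: Iterable[PPIEdgeRecord],
    domain_occurrences: Iterable[DomainOccurrence],
    ddi_templates: Iterable[tuple[str, str]] = (),
    dmi_records: Iterable[tuple[str, str, str, int, int]] = (),
    residue_records: Iterable[tuple[str, tuple[int, ...], str, tuple[int, ...]]] = (),
    predicted_ddis: Mapping[tuple[str, str], str] | None = None,
    tier_filter: Iterable[str] | None = None,
) -> JointNetwork:
    """Annotate distinct PPI pairs with all attaching domain-level evidence.

    A predicted DDI identical to an experimental template is kept once, as
    experimental. Homodimer edges attach each unordered domain pair once.
    Evidence records naming proteins absent from the PPI set (or an edge
    that does not exist) are skipped and counted.
    """
    tiers = _normalize_tier_filter(tier_filter)
    templates = {canonical_pair(a, b) for a, b in ddi_templates}
    predictions = {
        canonical_pair(*pair): tier
        for pair, tier in (predicted_ddis or {}).items()
        if canonical_pair(*pair) not in templates and tier in tiers
    }

    pairs: set[tuple[str, str]] = set()
    proteins: set[str] = set()
    for rec in ppi_edges:
        pairs.add(rec.key)
        proteins.update(rec.key)

    domains: dict[str, set[str]] = defaultdict(set)
    transcript_to_protein: dict[str, str] = {}
    for occ in domain_occurrences:
        domains[occ.protein_id].add(occ.domain_id)
        transcript_to_protein[occ.transcript_id] = occ.protein_id

    evidence: dict[tuple[str, str], list[EvidenceItem]] = defaultdict(list)

    def _ddi_items(pa: str, pb: str) -> Iterable[EvidenceItem]:
        if pa == pb:
            combos: Iterable[tuple[str, str]] = combinations_with_replacement(
                sorted(domains[pa]), 2)
        else:
            combos = product(sorted(domains[pa]), sorted(domains[pb]))
        seen = set()
        for a, b in combos:
            if (a, b) in seen:
                continue
            seen.add((a, b))
            pair = canonical_pair(a, b)
            if pair in templates:
                yield EvidenceItem(kind=DDI_EXPERIMENTAL, domain_a=a, domain_b=b)
            elif pair in predictions:
                yield EvidenceItem(kind=DDI_PREDICTED, domain_a=a, domain_b=b,
                                   tier=predictions[pair])

    for pa, pb in pairs:
        evidence[(pa, pb)].extend(_ddi_items(pa, pb))

    skipped = 0
    for dom_host, dom, motif_host, ms, me in dmi_records:
        if dom_host not in proteins or motif_host not in proteins:
            skipped += 1
            continue
        key = canonical_pair(dom_host, motif_host)
        if key not in pairs or dom not in domains[dom_host]:
            skipped += 1
            continue
        evidence[key].append(EvidenceItem(
            kind=DMI, domain_a=dom, motif_span=(ms, me),
            domain_on_a=(dom_host == key[0]),
        ))

    for prot_a, pos_a, prot_b, pos_b in residue_records:
        if prot_a not in proteins or prot_b not in proteins:
            skipped += 1
            continue
        key = canonical_pair(prot_a, prot_b)
        if key not in pairs:
            skipped += 1
            continue
        if key == (prot_a, prot_b):
            ra, rb = tuple(pos_a), tuple(pos_b)
        else:
            ra, rb = tuple(pos_b), tuple(pos_a)
        evidence[key].append(EvidenceItem(
            kind=RESIDUE, residue_positions_a=ra, residue_positions_b=rb,
        ))

    edges = {}
    unannotated = set()
    for key in pairs:
        items = evidence.get(key, [])
        if items:
            edges[key] = AnnotatedEdge(key[0], key[1], tuple(items))
        else:
            unannotated.add(key)
    if skipped:
        logger.warning("skipped %d DMI/residue records naming unknown proteins/edges",
                       skipped)
    return JointNetwork(
        proteins=proteins,
        edges=edges,
        unannotated_edges=unannotated,
        domains_by_protein={p: frozenset(d) for p, d in domains.items()},
        transcript_to_protein=transcript_to_protein,
        provenance={"tier_filter": sorted(tiers)},
        skipped_records=skipped,
    )


def isoform_view(
    network: JointNetwork,
    transcript_id: str,
    transcript_domain_set: Iterable[str],
) -> dict[tuple[str, str], dict]:
    """Partition evidence of edges incident to a transcript's parent protein.

    An evidence item is retained iff every domain it references on the
    parent protein is present in ``transcript_domain_set``; an edge is
    classified lost iff no evidence is retained. Motif/residue references
    are not domain-based and are always retained by this view.
    """
    if transcript_id not in network.transcript_to_protein:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    parent = network.transcript_to_protein[transcript_id]
    kept_domains = set(transcript_domain_set)
    extra = kept_domains - set(network.domains_by_protein.get(parent, frozenset()))
    if extra:
        raise ValueError(f"domains {sorted(extra)} not annotated on protein {parent}")

    report = {}
    for key, edge in network.edges.items():
        if parent not in key:
            continue
        retained, lost = [], []
        for item in edge.evidence:
            refs = []
            if item.kind in (DDI_EXPERIMENTAL, DDI_PREDICTED):
                if key[0] == parent:
                    refs.append(item.domain_a)
                if key[1] == parent:
                    refs.append(item.domain_b)
            elif item.kind == DMI:
                dom_host = key[0] if item.domain_on_a else key[1]
                if dom_host == parent:
                    refs.append(item.domain_a)
            (retained if all(r in kept_domains for r in refs) else lost).append(item)
        report[key] = {
            "retained": tuple(retained),
            "lost": tuple(lost),
            "edge_lost": not retained,
        }
    return report


def network_characteristics(
    network: JointNetwork,
    gene_sets: Sequence[PathwayGeneSet],
    protein_to_gene: Mapping[str, str],
) -> NetworkStats:
    """Compute N (annotated edges) and per-pathway incident-edge counts K.

    K(P) counts annotated edges with >= 1 endpoint mapping to a gene of P;
    an edge is counted once even when both endpoints are members. Proteins
    without a gene mapping are excluded from K and counted.
    """
    unmapped = {p for p in network.proteins if p not in protein_to_gene}
    if unmapped:
        logger.warning("%d network proteins lack a gene mapping", len(unmapped))
    edge_genes = {
        key: frozenset(protein_to_gene[p] for p in key if p in protein_to_gene)
        for key in network.edges
    }
    k_per_pathway = {}
    for gs in gene_sets:
        k_per_pathway[gs.pathway_id] = sum(
            1 for genes in edge_genes.values() if genes & gs.genes
        )
    return NetworkStats(
        n_edges_annotated=len(network.edges),
        n_proteins=len(network.proteins),
        k_per_pathway=k_per_pathway,
        unmapped_proteins=len(unmapped),
    )


# ---------------------------------------------------------------------------
# Export


def _evidence_dict(item: EvidenceItem) -> dict:
    d = {"kind": item.kind}
    if item.domain_a is not None:
        d["domain_a"] = item.domain_a
    if item.domain_b is not None:
        d["domain_b"] = item.domain_b
    if item.motif_span is not None:
        d["motif_span"] = list(item.motif_span)
        d["domain_on_a"] = item.domain_on_a
    if item.residue_positions_a:
        d["residue_positions_a"] = list(item.residue_positions_a)
        d["residue_positions_b"] = list(item.residue_positions_b)
    if item.tier != "n/a":
        d["tier"] = item.tier
    return d


def export_network_json(network: JointNetwork, path: str | Path) -> None:
    doc = {
        "proteins": sorted(network.proteins),
        "provenance": network.provenance,
        "edges": [
            {"protein_a": k[0], "protein_b": k[1],
             "evidence": [_evidence_dict(it) for it in network.edges[k].evidence]}
            for k in sorted(network.edges)
        ],
        "unannotated_edges": [list(k) for k in sorted(network.unannotated_edges)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def export_edge_evidence_tsv(network: JointNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tkind\tdomain_a\tdomain_b\ttier\n")
        for key in sorted(network.edges):
            for it in network.edges[key].evidence:
                fh.write("\t".join([
                    key[0], key[1], it.kind, it.domain_a or ".", it.domain_b or ".",
                    it.tier,
                ]) + "\n")
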