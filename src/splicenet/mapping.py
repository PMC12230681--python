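"""Event filtering, protein<->genomic coordinate lifting, and feature mapping.

Amino acid ``i`` of a protein covers coding nucleotides ``3i-2 .. 3i``
counted 5'->3' along the spliced CDS; footprints are returned as maximal
genomic runs in ascending order, which may span splice junctions. Overlap
between a splice event and a feature footprint is genomic intersection of
at least one nucleotide — no reading-frame checks.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    AffectedEdgeSet,
    AffectedFeatures,
    DomainOccurrence,
    DMI,
    JointNetwork,
    RESIDUE,
    SpliceEvent,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "filter_events",
    "protein_to_genomic",
    "genomic_to_protein",
    "compute_domain_footprints",
    "map_event_to_features",
    "map_events_to_features",
    "derive_affected_edges",
    "summarize_affected_features",
    "affected_features_frame",
    "affected_edges_frame",
]

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# Event filtering


def filter_events(
    events: Iterable[SpliceEvent], dpsi_min: float = 0.05, p_max: float = 0.05
) -> list[SpliceEvent]:
    """Keep events with |delta_psi| >= dpsi_min and significance <= p_max.

    Comparisons are inclusive; both signs of delta_psi are retained.
    """
    if not 0.0 <= dpsi_min <= 1.0 or not 0.0 <= p_max <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    return [e for e in events
            if abs(e.delta_psi) >= dpsi_min and e.significance <= p_max]


# ---------------------------------------------------------------------------
# Coordinate lifting


def _cds_in_transcription_order(tm: TranscriptModel) -> list[Interval]:
    return list(tm.cds) if tm.strand == "+" else list(reversed(tm.cds))


def _merge_runs(ivals: list[Interval]) -> tuple[Interval, ...]:
    """Sort ascending and merge genomically adjacent or overlapping runs."""
    merged: list[Interval] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def protein_to_genomic(
    tm: TranscriptModel, aa_start: int, aa_end: int
) -> tuple[Interval, ...]:
    """Lift a 1-based inclusive amino-acid interval to genomic intervals."""
    if not tm.cds:
        raise ValueError(f"transcript {tm.transcript_id} has no CDS")
    if not 1 <= aa_start <= aa_end:
        raise ValueError("require 1 <= aa_start <= aa_end")
    if aa_end * 3 > tm.cds_length:
        raise ValueError(
            f"aa_end {aa_end} beyond protein length {tm.cds_length // 3} "
            f"of transcript {tm.transcript_id}"
        )
    c1, c2 = 3 * aa_start - 2, 3 * aa_end  # coding-offset window, 1-based
    out: list[Interval] = []
    cum = 0
    for s, e in _cds_in_transcription_order(tm):
        length = e - s + 1
        lo, hi = max(c1, cum + 1), min(c2, cum + length)
        if lo <= hi:
            if tm.strand == "+":
                out.append((s + (lo - cum - 1), s + (hi - cum - 1)))
            else:
                out.append((e - (hi - cum - 1), e - (lo - cum - 1)))
        cum += length
    return _merge_runs(out)


def genomic_to_protein(
    tm: TranscriptModel, interval: Interval
) -> tuple[int, int] | None:
    """Return the minimal aa interval covering the CDS overlap of ``interval``.

    Returns None when the interval does not intersect the CDS.
    """
    if not tm.cds:
        raise ValueError(f"transcript {tm.transcript_id} has no CDS")
    g1, g2 = interval
    if g1 > g2:
        raise ValueError("reversed genomic interval")
    lo_off = hi_off = None
    cum = 0
    for s, e in _cds_in_transcription_order(tm):
        length = e - s + 1
        a, b = max(g1, s), min(g2, e)
        if a <= b:
            if tm.strand == "+":
                off1, off2 = cum + (a - s) + 1, cum + (b - s) + 1
            else:
                off1, off2 = cum + (e - b) + 1, cum + (e - a) + 1
            lo_off = off1 if lo_off is None else min(lo_off, off1)
            hi_off = off2 if hi_off is None else max(hi_off, off2)
        cum += length
    if lo_off is None:
        return None
    return ((lo_off + 2) // 3, (hi_off + 2) // 3)


def compute_domain_footprints(
    occurrences: Iterable[DomainOccurrence],
    transcript_models: Iterable[TranscriptModel],
) -> list[DomainOccurrence]:
    """Attach genomic footprints to domain occurrences via their transcripts.

    Occurrences on transcripts without a clean CDS (missing, length not
    divisible by 3, or too short for the domain) keep an empty footprint and
    are logged; they still participate in protein-level network annotation.
    """
    by_tid = {tm.transcript_id: tm for tm in transcript_models}
    out = []
    for occ in occurrences:
        tm = by_tid.get(occ.transcript_id)
        if tm is None or not tm.cds or tm.cds_length % 3 != 0 \
                or occ.aa_end * 3 > tm.cds_length:
            logger.warning(
                "domain %s on %s/%s: no liftable CDS; footprint left empty",
                occ.domain_id, occ.protein_id, occ.transcript_id,
            )
            out.append(occ)
            continue
        out.append(occ.with_footprint(protein_to_genomic(tm, occ.aa_start, occ.aa_end)))
    return out


# ---------------------------------------------------------------------------
# Event -> feature mapping


def _overlap_nt(interval: Interval, segments: Sequence[Interval]) -> int:
    s, e = interval
    return sum(max(0, min(e, b) - max(s, a) + 1) for a, b in segments)


def map_event_to_features(
    event: SpliceEvent,
    transcript_models: Sequence[TranscriptModel],
    domain_occurrences: Sequence[DomainOccurrence],
    motif_records: Sequence[tuple[str, str, str, int, int]] = (),
    residue_records: Sequence[tuple[str, tuple[int, ...], str, tuple[int, ...]]] = (),
) -> AffectedFeatures:
    """Map one event onto domains, motifs and residues via genomic overlap.

    A feature is affected iff its genomic footprint intersects the event
    exon interval by >= 1 nt on a transcript of the event's gene; the event
    maps through every transcript whose exon set intersects it, not only a
    canonical one.
    """
    res = AffectedFeatures(event=event)
    ev_iv = (event.exon_start, event.exon_end)
    gene_models = [tm for tm in transcript_models
                   if tm.gene_id == event.gene_id and tm.chrom == event.chrom]
    if not gene_models:
        res.unmapped = True
        return res
    hit_models = [tm for tm in gene_models if _overlap_nt(ev_iv, tm.exons) > 0]
    res.transcripts = [tm.transcript_id for tm in hit_models]
    hit_tids = set(res.transcripts)
    liftable = {tm.transcript_id: tm for tm in hit_models
                if tm.cds and tm.cds_length % 3 == 0}
    protein_of = {tid: tm.protein_id or tm.gene_id for tid, tm in liftable.items()}
    tids_of_protein = defaultdict(list)
    for tid, pid in protein_of.items():
        tids_of_protein[pid].append(tid)

    for occ in domain_occurrences:
        if occ.transcript_id not in hit_tids or not occ.genomic_footprint:
            continue
        nt = _overlap_nt(ev_iv, occ.genomic_footprint)
        if nt > 0:
            res.domains.append((occ, nt))
            res.genes.add(event.gene_id)

    for _dom_host, _dom, motif_host, ms, me in motif_records:
        for tid in tids_of_protein.get(motif_host, ()):
            tm = liftable[tid]
            if me * 3 > tm.cds_length:
                continue
            nt = _overlap_nt(ev_iv, protein_to_genomic(tm, ms, me))
            if nt > 0:
                res.motifs.append((motif_host, tid, ms, me, nt))
                res.genes.add(event.gene_id)

    for prot_a, pos_a, prot_b, pos_b in residue_records:
        for prot, positions in ((prot_a, pos_a), (prot_b, pos_b)):
            for tid in tids_of_protein.get(prot, ()):
                tm = liftable[tid]
                for pos in positions:
                    if pos * 3 > tm.cds_length:
                        continue
                    nt = _overlap_nt(ev_iv, protein_to_genomic(tm, pos, pos))
                    if nt > 0:
                        res.residues.append((prot, tid, pos, nt))
                        res.genes.add(event.gene_id)
    return res


def map_events_to_features(
    events: Iterable[SpliceEvent],
    transcript_models: Sequence[TranscriptModel],
    domain_occurrences: Sequence[DomainOccurrence],
    motif_records: Sequence[tuple[str, str, str, int, int]] = (),
    residue_records: Sequence[tuple[str, tuple[int, ...], str, tuple[int, ...]]] = (),
) -> list[AffectedFeatures]:
    out = []
    n_unmapped = 0
    for ev in events:
        feats = map_event_to_features(
            ev, transcript_models, domain_occurrences, motif_records, residue_records
        )
        if feats.unmapped:
            n_unmapped += 1
        out.append(feats)
    if n_unmapped:
        logger.warning("%d events had no transcript model for their gene", n_unmapped)
    return out


# ---------------------------------------------------------------------------
# Affected edges


def derive_affected_edges(
    network: JointNetwork, features: Iterable[AffectedFeatures]
) -> AffectedEdgeSet:
    """Intersect affected features with edge evidence to find rewired edges.

    An evidence item is lost iff it references an affected domain on the
    matching endpoint (DDI), an affected motif span (DMI), or >= 1 affected
    residue position; an edge is affected iff it loses >= 1 item.
    """
    dom_events: dict[tuple[str, str], set[str]] = defaultdict(set)
    motif_events: dict[tuple[str, int, int], set[str]] = defaultdict(set)
    residue_events: dict[tuple[str, int], set[str]] = defaultdict(set)
    for feats in features:
        eid = feats.event.event_id
        for occ, _nt in feats.domains:
            dom_events[(occ.protein_id, occ.domain_id)].add(eid)
        for prot, _tid, ms, me, _nt in feats.motifs:
            motif_events[(prot, ms, me)].add(eid)
        for prot, _tid, pos, _nt in feats.residues:
            residue_events[(prot, pos)].add(eid)

    edges = {}
    events_by_edge = {}
    for key, edge in network.edges.items():
        pa, pb = key
        lost, kept = [], []
        edge_events: set[str] = set()
        for item in edge.evidence:
            hits: set[str] = set()
            if item.kind in ("ddi_experimental", "ddi_predicted"):
                hits |= dom_events.get((pa, item.domain_a), set())
                hits |= dom_events.get((pb, item.domain_b), set())
            elif item.kind == DMI:
                dom_host, motif_host = (pa, pb) if item.domain_on_a else (pb, pa)
                hits |= dom_events.get((dom_host, item.domain_a), set())
                hits |= motif_events.get((motif_host, *item.motif_span), set())
            elif item.kind == RESIDUE:
                for prot, positions in ((pa, item.residue_positions_a),
                                        (pb, item.residue_positions_b)):
                    for pos in positions:
                        hits |= residue_events.get((prot, pos), set())
            if hits:
                lost.append(item)
                edge_events |= hits
            else:
                kept.append(item)
        if lost:
            edges[key] = (tuple(lost), tuple(kept))
            events_by_edge[key] = tuple(sorted(edge_events))
    return AffectedEdgeSet(edges=edges, events_by_edge=events_by_edge)


# ---------------------------------------------------------------------------
# Summaries


def summarize_affected_features(features: Iterable[AffectedFeatures]) -> pd.DataFrame:
    """Distinct affected features per gene and kind (de-duplicated across events)."""
    seen: dict[tuple[str, str], set] = defaultdict(set)
    for feats in features:
        gene = feats.event.gene_id
        for occ, _nt in feats.domains:
            seen[(gene, "domain")].add((occ.protein_id, occ.domain_id))
        for prot, _tid, ms, me, _nt in feats.motifs:
            seen[(gene, "dmi")].add((prot, ms, me))
        for prot, _tid, pos, _nt in feats.residues:
            seen[(gene, "residue")].add((prot, pos))
    rows = [{"gene": g, "feature_kind": k, "n_features": len(v)}
            for (g, k), v in sorted(seen.items())]
    return pd.DataFrame(rows, columns=["gene", "feature_kind", "n_features"])


def affected_features_frame(features: Iterable[AffectedFeatures]) -> pd.DataFrame:
    """Flat per-feature table matching the affected_features.tsv schema."""
    rows = []
    for feats in features:
        eid, gene = feats.event.event_id, feats.event.gene_id
        for occ, nt in feats.domains:
            rows.append((eid, gene, occ.transcript_id, "domain", occ.domain_id, nt))
        for prot, tid, ms, me, nt in feats.motifs:
            rows.append((eid, gene, tid, "dmi", f"{prot}:motif:{ms}-{me}", nt))
        for prot, tid, pos, nt in feats.residues:
            rows.append((eid, gene, tid, "residue", f"{prot}:residue:{pos}", nt))
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene", "transcript", "feature_kind", "feature_id",
                 "overlap_nt"],
    )


def affected_edges_frame(affected: AffectedEdgeSet) -> pd.DataFrame:
    rows = []
    for key in sorted(affected.edges):
        lost, kept = affected.edges[key]
        rows.append((key[0], key[1], len(lost), len(kept),
                     ";".join(affected.events_by_edge[key])))
    return pd.DataFrame(
        rows,
        columns=["protein_a", "protein_b", "lost_evidence", "surviving_evidence",
                 "event_ids"],
    )
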