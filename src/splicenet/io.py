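"""Readers and writers for every external file format the pipeline touches.

All readers normalize coordinates to the internal 1-based inclusive
convention and identifiers to opaque strings; no online lookups are ever
performed. Malformed input raises :class:`FormatError` carrying the
offending line number.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    PathwayGeneSet,
    PPIEdgeRecord,
    DomainOccurrence,
    SpliceEvent,
    TranscriptModel,
    canonical_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_ppi_table",
    "read_transcript_models_gtf",
    "read_splice_events",
    "read_gene_sets_gmt",
    "read_domain_table",
    "read_ddi_templates",
    "read_predicted_ddis",
    "read_dmi_records",
    "read_residue_records",
    "read_protein_gene_map",
    "write_splice_events_bed",
    "write_results",
    "read_enrichment_table",
    "read_affected_features_table",
    "read_affected_edges_table",
    "SPLICE_DIALECTS",
    "ENRICHMENT_COLUMNS",
    "AFFECTED_FEATURES_COLUMNS",
    "AFFECTED_EDGES_COLUMNS",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


SPLICE_DIALECTS = ("rmats_se", "whippet", "majiq", "generic_bed")

ENRICHMENT_COLUMNS = [
    "pathway_id", "name", "database", "N", "K", "n", "k",
    "p_raw", "p_adj", "nease_score", "contributing_genes",
]
AFFECTED_FEATURES_COLUMNS = [
    "event_id", "gene", "transcript", "feature_kind", "feature_id", "overlap_nt",
]
AFFECTED_EDGES_COLUMNS = [
    "protein_a", "protein_b", "lost_evidence", "surviving_evidence", "event_ids",
]

_HEADER_HINT = re.compile(r"protein|interactor|gene|symbol|domain", re.IGNORECASE)


def _lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping blanks/comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            yield lineno, fields


# ---------------------------------------------------------------------------
# PPI tables


def read_ppi_table(path: str | Path, resource_name: str) -> list[PPIEdgeRecord]:
    """Read a two-column PPI edge list for one resource.

    Unordered duplicate pairs are collapsed; a header line is detected by
    name sniffing (any field matching protein/interactor/gene).
    """
    seen: dict[tuple[str, str], PPIEdgeRecord] = {}
    n_dup = 0
    first = True
    for lineno, fields in _lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: PPI row needs >= 2 columns, got {len(fields)}")
        if first:
            first = False
            if _HEADER_HINT.search(fields[0]) or _HEADER_HINT.search(fields[1]):
                continue
        rec = PPIEdgeRecord(fields[0], fields[1], resource_name)
        if rec.key in seen:
            n_dup += 1
        else:
            seen[rec.key] = rec
    if n_dup:
        logger.info("%s: collapsed %d duplicate unordered pairs", path, n_dup)
    if not seen:
        logger.warning("%s: empty PPI table for resource %s", path, resource_name)
    return list(seen.values())


# ---------------------------------------------------------------------------
# GTF transcript models


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_transcript_models_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon and CDS features from a GTF file into transcript models.

    GTF coordinates are 1-based inclusive and kept as such. Transcripts
    whose CDS falls outside their exon envelope are skipped with a warning;
    CDS lengths not divisible by 3 are logged (the transcript is kept but
    will be excluded from protein-coordinate lifting downstream).
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str | None]] = {}
    for lineno, fields in _lines(path):
        if len(fields) < 9:
            raise FormatError(f"{path}:{lineno}: GTF row needs 9 columns")
        chrom, _src, feature, start, end, _score, strand, _frame = fields[:8]
        if feature not in ("exon", "CDS"):
            continue
        attrs = dict(_GTF_ATTR.findall(fields[8]))
        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id")
        if not tid or not gid:
            raise FormatError(f"{path}:{lineno}: missing gene_id/transcript_id attribute")
        ival = (int(start), int(end))
        pid = attrs.get("protein_id")
        prev = meta.get(tid)
        meta[tid] = (gid, chrom, strand, pid or (prev[3] if prev else None))
        (exons if feature == "exon" else cds).setdefault(tid, []).append(ival)

    models = []
    for tid, (gid, chrom, strand, pid) in sorted(meta.items()):
        ex = tuple(sorted(exons.get(tid, [])))
        cd = tuple(sorted(cds.get(tid, [])))
        if not ex:
            logger.warning("transcript %s has CDS but no exons; skipped", tid)
            continue
        if not all(any(es <= cs and ce <= ee for es, ee in ex) for cs, ce in cd):
            logger.warning("transcript %s: CDS outside exon envelope; skipped", tid)
            continue
        model = TranscriptModel(tid, gid, chrom, strand, ex, cd, protein_id=pid)
        if pid and model.cds_length % 3 != 0:
            logger.warning(
                "transcript %s: CDS length %d not divisible by 3; kept for exon "
                "overlap only", tid, model.cds_length,
            )
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Splice event dialects


def _require(header: dict[str, int], cols: Sequence[str], path, dialect: str) -> None:
    for col in cols:
        if col not in header:
            raise FormatError(f"{path}: dialect {dialect!r} requires column {col!r}")


def _clamp_sig(x: float) -> float:
    return min(1.0, max(0.0, x))


def read_splice_events(
    path: str | Path,
    dialect: str,
    condition_labels: tuple[str, str] = ("A", "B"),
    significance_column: str | None = None,
) -> list[SpliceEvent]:
    """Read differential exon-skipping events in one of the supported dialects.

    Dialects: ``rmats_se`` (SE.MATS.JC.txt; significance from PValue, or FDR
    via ``significance_column``), ``whippet`` (.diff; Type == CE rows only,
    significance = 1 - Probability), ``majiq`` (delta-PSI table,
    significance = 1 - P(|dPSI| >= 0.2)), and headerless ``generic_bed``
    (chrom, start0, end, gene_id, delta_psi, strand, significance).
    All coordinates are normalized to 1-based inclusive.
    """
    if dialect not in SPLICE_DIALECTS:
        raise FormatError(f"unknown splice dialect {dialect!r}; expected one of {SPLICE_DIALECTS}")
    rows = list(_lines(path))
    events: list[SpliceEvent] = []

    if dialect == "generic_bed":
        for lineno, fields in rows:
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: generic_bed needs 7 columns")
            chrom, start0, end, gene, dpsi, strand, sig = fields[:7]
            events.append(SpliceEvent(
                gene_id=gene, chrom=chrom, strand=strand,
                exon_start=int(start0) + 1, exon_end=int(end),
                delta_psi=float(dpsi), significance=float(sig), dialect=dialect,
            ))
        return events

    if not rows:
        logger.warning("%s: empty splice event table", path)
        return events
    header = {name: i for i, name in enumerate(rows[0][1])}
    body = rows[1:]

    if dialect == "rmats_se":
        sig_col = significance_column or "PValue"
        _require(header, ["GeneID", "chr", "strand", "exonStart_0base", "exonEnd",
                          "IncLevelDifference", sig_col], path, dialect)
        for lineno, fields in body:
            try:
                events.append(SpliceEvent(
                    gene_id=fields[header["GeneID"]].strip('"'),
                    chrom=fields[header["chr"]],
                    strand=fields[header["strand"]],
                    exon_start=int(fields[header["exonStart_0base"]]) + 1,
                    exon_end=int(fields[header["exonEnd"]]),
                    delta_psi=float(fields[header["IncLevelDifference"]]),
                    significance=float(fields[header[sig_col]]),
                    dialect=dialect,
                ))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed rMATS row: {exc}") from exc
    elif dialect == "whippet":
        _require(header, ["Gene", "Coord", "Strand", "Type", "DeltaPsi", "Probability"],
                 path, dialect)
        coord_re = re.compile(r"^(.+):(\d+)-(\d+)$")
        for lineno, fields in body:
            if fields[header["Type"]] != "CE":
                continue
            m = coord_re.match(fields[header["Coord"]])
            if not m:
                raise FormatError(f"{path}:{lineno}: bad Coord field {fields[header['Coord']]!r}")
            events.append(SpliceEvent(
                gene_id=fields[header["Gene"]],
                chrom=m.group(1), strand=fields[header["Strand"]],
                exon_start=int(m.group(2)), exon_end=int(m.group(3)),
                delta_psi=float(fields[header["DeltaPsi"]]),
                significance=_clamp_sig(1.0 - float(fields[header["Probability"]])),
                dialect=dialect,
            ))
    else:  # majiq
        _require(header, ["gene_id", "chrom", "strand", "exon_start", "exon_end",
                          "e_dpsi", "p_changing"], path, dialect)
        for lineno, fields in body:
            events.append(SpliceEvent(
                gene_id=fields[header["gene_id"]],
                chrom=fields[header["chrom"]],
                strand=fields[header["strand"]],
                exon_start=int(fields[header["exon_start"]]),
                exon_end=int(fields[header["exon_end"]]),
                delta_psi=float(fields[header["e_dpsi"]]),
                significance=_clamp_sig(1.0 - float(fields[header["p_changing"]])),
                dialect=dialect,
            ))
    return events


def write_splice_events_bed(events: Iterable[SpliceEvent], path: str | Path) -> None:
    """Write events in the headerless generic_bed dialect (round-trippable)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write("\t".join([
                ev.chrom, str(ev.exon_start - 1), str(ev.exon_end), ev.gene_id,
                repr(ev.delta_psi), ev.strand, repr(ev.significance),
            ]) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets_gmt(path: str | Path, database_label: str) -> list[PathwayGeneSet]:
    """Read a GMT file (name, description, member genes...)."""
    sets: dict[str, PathwayGeneSet] = {}
    for lineno, fields in _lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        pid, desc, genes = fields[0], fields[1], frozenset(g for g in fields[2:] if g)
        if pid in sets:
            raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
        if not genes:
            logger.warning("%s:%d: pathway %s has no genes; dropped", path, lineno, pid)
            continue
        sets[pid] = PathwayGeneSet(pid, desc, database_label, genes)
    return list(sets.values())


# ---------------------------------------------------------------------------
# Evidence tables (pre-extracted TSVs)


def read_domain_table(path: str | Path) -> list[DomainOccurrence]:
    """Read domain occurrences: protein_id, transcript_id, domain_id, aa_start, aa_end."""
    out = []
    first = True
    for lineno, fields in _lines(path):
        if len(fields) < 5:
            raise FormatError(f"{path}:{lineno}: domain row needs 5 columns")
        if first:
            first = False
            if _HEADER_HINT.search(fields[0]):
                continue
        try:
            out.append(DomainOccurrence(
                protein_id=fields[0], transcript_id=fields[1], domain_id=fields[2],
                aa_start=int(fields[3]), aa_end=int(fields[4]),
            ))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed domain row: {exc}") from exc
    return out


def read_ddi_templates(path: str | Path) -> set[tuple[str, str]]:
    """Read experimental DDI templates as canonical domain pairs."""
    pairs = set()
    first = True
    for lineno, fields in _lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: DDI template row needs 2 columns")
        if first:
            first = False
            if _HEADER_HINT.search(fields[0]):
                continue
        pairs.add(canonical_pair(fields[0], fields[1]))
    return pairs


def read_predicted_ddis(path: str | Path) -> dict[tuple[str, str], str]:
    """Read predicted DDIs: domain_a, domain_b, tier [, score...]."""
    preds = {}
    first = True
    for lineno, fields in _lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: predicted DDI row needs 3 columns")
        if first:
            first = False
            if _HEADER_HINT.search(fields[0]) or fields[2] == "tier":
                continue
        tier = fields[2]
        if tier not in ("gold", "silver", "bronze"):
            raise FormatError(f"{path}:{lineno}: unknown tier {tier!r}")
        preds[canonical_pair(fields[0], fields[1])] = tier
    return preds


def read_dmi_records(path: str | Path) -> list[tuple[str, str, str, int, int]]:
    """Read DMIs: protein_with_domain, domain_id, protein_with_motif, motif_start, motif_end."""
    out = []
    first = True
    for lineno, fields in _lines(path):
        if len(fields) < 5:
            raise FormatError(f"{path}:{lineno}: DMI row needs 5 columns")
        if first:
            first = False
            if _HEADER_HINT.search(fields[0]):
                continue
        out.append((fields[0], fields[1], fields[2], int(fields[3]), int(fields[4])))
    return out


def read_residue_records(path: str | Path) -> list[tuple[str, tuple[int, ...], str, tuple[int, ...]]]:
    """Read residue evidence: protein_a, positions_a (comma list), protein_b, positions_b."""
    out = []
    first = True
    for lineno, fields in _lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: residue row needs 4 columns")
        if first:
            first = False
            if _HEADER_HINT.search(fields[0]):
                continue
        try:
            pos_a = tuple(int(x) for x in fields[1].split(",") if x)
            pos_b = tuple(int(x) for x in fields[3].split(",") if x)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed residue positions: {exc}") from exc
        out.append((fields[0], pos_a, fields[2], pos_b))
    return out


def read_protein_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column protein_id -> gene_id mapping."""
    mapping = {}
    first = True
    for lineno, fields in _lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: mapping row needs 2 columns")
        if first:
            first = False
            if _HEADER_HINT.search(fields[0]):
                continue
        mapping[fields[0]] = fields[1]
    return mapping


# ---------------------------------------------------------------------------
# Result tables


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def write_results(tables: dict, out_dir: str | Path) -> dict:
    """Write result tables to ``out_dir`` deterministically; return a manifest.

    Recognized keys: ``enrichment`` (DataFrame), ``affected_features``
    (DataFrame), ``affected_edges`` (DataFrame), ``pathway_detail`` (dict of
    pathway_id -> DataFrame). Rows are sorted with documented tie-breaks:
    enrichment by (p_adj, pathway_id), other tables by all columns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": []}

    def _emit(df: pd.DataFrame, name: str, sort_by: list[str]) -> None:
        dest = out_dir / name
        df.sort_values(sort_by, kind="mergesort").to_csv(dest, sep="\t", index=False)
        manifest["files"].append(name)

    if "enrichment" in tables:
        df = _check_columns(tables["enrichment"], ENRICHMENT_COLUMNS, "enrichment")
        _emit(df[ENRICHMENT_COLUMNS], "enrichment.tsv", ["p_adj", "pathway_id"])
    if "affected_features" in tables:
        df = _check_columns(tables["affected_features"], AFFECTED_FEATURES_COLUMNS,
                            "affected_features")
        _emit(df[AFFECTED_FEATURES_COLUMNS], "affected_features.tsv",
              AFFECTED_FEATURES_COLUMNS)
    if "affected_edges" in tables:
        df = _check_columns(tables["affected_edges"], AFFECTED_EDGES_COLUMNS,
                            "affected_edges")
        _emit(df[AFFECTED_EDGES_COLUMNS], "affected_edges.tsv", ["protein_a", "protein_b"])
    for pid, df in sorted(tables.get("pathway_detail", {}).items()):
        safe = re.sub(r"[^\w.-]", "_", pid)
        _emit(df, f"pathway_detail_{safe}.tsv", list(df.columns))

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["files"].append("manifest.json")
    return manifest


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path, sep="\t"), ENRICHMENT_COLUMNS, path)


def read_affected_features_table(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path, sep="\t"), AFFECTED_FEATURES_COLUMNS, path)


def read_affected_edges_table(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path, sep="\t"), AFFECTED_EDGES_COLUMNS, path)
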