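"""End-to-end orchestration: build -> filter -> map -> derive -> enrich."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import enrichment as enr
from . import io as fio
from . import mapping, network

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run.

    Default thresholds: |delta_psi| >= 0.05 and significance <= 0.05;
    predicted DDIs are off unless a tier filter is given.
    """

    gtf: str
    domains: str
    events: str
    gene_sets: str
    protein_gene_map: str
    out_dir: str
    ppi_tables: dict[str, str] = field(default_factory=dict)  # resource -> path
    ddi_templates: str | None = None
    predicted_ddis: str | None = None
    dmi_records: str | None = None
    residue_records: str | None = None
    event_dialect: str = "generic_bed"
    database_label: str = "custom"
    organism_label: str = "synthetic"
    dpsi_min: float = 0.05
    p_max: float = 0.05
    tier_filter: tuple[str, ...] = ()
    significance_cutoff: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        required = [self.gtf, self.domains, self.events, self.gene_sets,
                    self.protein_gene_map, *self.ppi_tables.values()]
        for opt in (self.ddi_templates, self.predicted_ddis, self.dmi_records,
                    self.residue_records):
            if opt:
                required.append(opt)
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise PipelineError(f"missing input file(s): {missing}")
        if not self.ppi_tables:
            raise PipelineError("at least one PPI table is required")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; write result tables and run metadata.

    Returns the output manifest. On any stage failure a FAILED marker is
    written next to whatever partial outputs exist and the error re-raised.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    try:
        manifest = _run(config, out_dir, counts)
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return manifest


def _run(config: RunConfig, out_dir: Path, counts: dict) -> dict:
    models = fio.read_transcript_models_gtf(config.gtf)
    occurrences = fio.read_domain_table(config.domains)
    occurrences = mapping.compute_domain_footprints(occurrences, models)
    counts["transcripts"] = len(models)
    counts["domain_occurrences"] = len(occurrences)

    ppi_edges = []
    for resource, path in sorted(config.ppi_tables.items()):
        ppi_edges.extend(fio.read_ppi_table(path, resource))
    counts["ppi_records"] = len(ppi_edges)

    templates = fio.read_ddi_templates(config.ddi_templates) if config.ddi_templates else set()
    predicted = fio.read_predicted_ddis(config.predicted_ddis) if config.predicted_ddis else {}
    dmis = fio.read_dmi_records(config.dmi_records) if config.dmi_records else []
    residues = fio.read_residue_records(config.residue_records) if config.residue_records else []

    net = network.build_joint_network(
        ppi_edges, occurrences, templates, dmis, residues, predicted,
        tier_filter=config.tier_filter,
    )
    counts["edges_annotated"] = net.n_annotated
    counts["edges_unannotated"] = len(net.unannotated_edges)
    network.export_network_json(net, out_dir / "network.json")
    network.export_edge_evidence_tsv(net, out_dir / "edge_evidence.tsv")

    events = fio.read_splice_events(config.events, config.event_dialect)
    significant = mapping.filter_events(events, config.dpsi_min, config.p_max)
    counts["events_read"] = len(events)
    counts["events_significant"] = len(significant)

    features = mapping.map_events_to_features(significant, models, occurrences,
                                              dmis, residues)
    counts["events_with_features"] = sum(1 for f in features if not f.is_empty)
    affected = mapping.derive_affected_edges(net, features)
    counts["edges_affected"] = affected.n

    gene_sets = fio.read_gene_sets_gmt(config.gene_sets, config.database_label)
    protein_to_gene = fio.read_protein_gene_map(config.protein_gene_map)
    stats = network.network_characteristics(net, gene_sets, protein_to_gene)
    results = enr.enrich_pathways(stats, affected, gene_sets, protein_to_gene)
    counts["pathways_tested"] = len(results)
    counts["pathways_significant"] = sum(
        1 for r in results if r.p_adj <= config.significance_cutoff)

    detail_tables = {}
    by_id = {gs.pathway_id: gs for gs in gene_sets}
    for res in results:
        if res.p_adj <= config.significance_cutoff and res.k_affected > 0:
            detail = enr.pathway_detail(net, affected, by_id[res.pathway_id],
                                        protein_to_gene)
            detail_tables[res.pathway_id] = _detail_frame(detail)
    graph = enr.pathway_cluster_graph(results, config.significance_cutoff)
    enr.export_cluster_graph(graph, out_dir / "pathway_clusters.tsv",
                             out_dir / "pathway_clusters.json")

    manifest = fio.write_results({
        "enrichment": enr.enrichment_frame(results),
        "affected_features": mapping.affected_features_frame(features),
        "affected_edges": mapping.affected_edges_frame(affected),
        "pathway_detail": detail_tables,
    }, out_dir)
    manifest["files"].extend(["network.json", "edge_evidence.tsv",
                              "pathway_clusters.tsv", "pathway_clusters.json"])

    _check_counts(counts)
    metadata = {
        "config": dataclasses.asdict(config),
        "counts": counts,
        "outputs": sorted(manifest["files"]),
    }
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    manifest["files"].append("run_metadata.json")
    manifest["counts"] = counts
    return manifest


def _detail_frame(detail):
    import pandas as pd

    rows = [{
        "gene": gene,
        "member_of_pathway": member,
        "partners_in_pathway": ";".join(partners),
        "lost_evidence_kinds": ";".join(kinds),
    } for gene, member, partners, kinds in detail.rows]
    return pd.DataFrame(rows, columns=[
        "gene", "member_of_pathway", "partners_in_pathway", "lost_evidence_kinds",
    ])


def _check_counts(counts: dict) -> None:
    """Internal consistency of stage counts; violations are pipeline bugs."""
    assert counts["events_significant"] <= counts["events_read"]
    assert counts["events_with_features"] <= counts["events_significant"]
    assert counts["edges_affected"] <= counts["edges_annotated"]
    assert counts["pathways_significant"] <= counts["pathways_tested"]
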