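"""Edge-level hypergeometric pathway enrichment over rewired edges.

The population is the set of annotated edges (N); K edges are incident to
a pathway, n edges are affected by splicing, k of those are incident. The
raw p-value is the inclusive upper tail P(X >= k); Benjamini-Hochberg is
applied across all testable pathways of one database and results are
ranked by a -log10(adjusted p) score.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import (
    AffectedEdgeSet,
    EnrichmentResult,
    JointNetwork,
    NetworkStats,
    PathwayDetail,
    PathwayGeneSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "edge_level_test",
    "adjust_bh",
    "enrich_pathways",
    "pathway_detail",
    "pathway_cluster_graph",
    "enrichment_frame",
    "export_cluster_graph",
]

_P_FLOOR = 1e-300  # guard for -log10 on underflowing adjusted p-values


def edge_level_test(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper-tail hypergeometric p-value P(X >= k).

    X counts pathway-incident edges among n affected edges drawn without
    replacement from N annotated edges of which K are pathway-incident.
    """
    for name, val in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not isinstance(val, (int, np.integer)) or val < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {val!r}")
    if K > N or n > N or k > min(n, K):
        raise ValueError(f"invalid configuration N={N}, K={K}, n={n}, k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    if len(p_values) == 0:
        return np.array([])
    return multipletests(p_values, method="fdr_bh")[1]


def _edge_gene_sets(
    edges: Sequence[tuple[str, str]], protein_to_gene: Mapping[str, str]
) -> dict[tuple[str, str], frozenset[str]]:
    return {
        key: frozenset(protein_to_gene[p] for p in key if p in protein_to_gene)
        for key in edges
    }


def enrich_pathways(
    network_stats: NetworkStats,
    affected: AffectedEdgeSet,
    gene_sets: Sequence[PathwayGeneSet],
    protein_to_gene: Mapping[str, str],
) -> list[EnrichmentResult]:
    """Run the edge-level test per pathway with BH correction.

    Pathways with K = 0 are untestable and excluded before correction.
    Results are sorted by (adjusted p, pathway_id).
    """
    N = network_stats.n_edges_annotated
    n = affected.n
    affected_genes = _edge_gene_sets(list(affected.edges), protein_to_gene)

    results = []
    for gs in gene_sets:
        if gs.pathway_id not in network_stats.k_per_pathway:
            raise KeyError(f"no K computed for pathway {gs.pathway_id!r}")
        K = network_stats.k_per_pathway[gs.pathway_id]
        if K == 0:
            logger.info("pathway %s untestable (K = 0); excluded", gs.pathway_id)
            continue
        incident = [key for key, genes in affected_genes.items() if genes & gs.genes]
        contributing: dict[str, int] = defaultdict(int)
        for key in incident:
            for gene in affected_genes[key]:
                contributing[gene] += 1
        results.append(EnrichmentResult(
            pathway_id=gs.pathway_id,
            pathway_name=gs.pathway_name,
            database_label=gs.database_label,
            n_population=N, k_pathway=K, n_affected=n, k_affected=len(incident),
            p_raw=edge_level_test(N, K, n, len(incident)),
            contributing_genes=dict(sorted(contributing.items())),
        ))

    if results:
        p_adj = adjust_bh([r.p_raw for r in results])
        for r, adj in zip(results, p_adj):
            r.p_adj = float(adj)
            r.nease_score = float(-np.log10(max(adj, _P_FLOOR)))
    results.sort(key=lambda r: (r.p_adj, r.pathway_id))
    return results


def pathway_detail(
    network: JointNetwork,
    affected: AffectedEdgeSet,
    pathway: PathwayGeneSet,
    protein_to_gene: Mapping[str, str],
) -> PathwayDetail:
    """Per-gene rewiring detail for one pathway.

    One row per gene contributing >= 1 affected edge incident to the
    pathway, flagged for membership, with its affected partner genes inside
    the pathway and the kinds of evidence lost.
    """
    rows_partners: dict[str, set[str]] = defaultdict(set)
    rows_kinds: dict[str, set[str]] = defaultdict(set)
    members: dict[str, bool] = {}
    for key, (lost, _kept) in affected.edges.items():
        genes = [protein_to_gene.get(p) for p in key]
        if not any(g in pathway.genes for g in genes if g):
            continue
        for i, gene in enumerate(genes):
            if gene is None:
                continue
            partner = genes[1 - i] if len(set(key)) > 1 else gene
            members[gene] = gene in pathway.genes
            if partner and partner in pathway.genes:
                rows_partners[gene].add(partner)
            else:
                rows_partners[gene]  # ensure row exists even with no inside partner
            rows_kinds[gene].update(it.kind for it in lost)
    detail = PathwayDetail(pathway_id=pathway.pathway_id)
    for gene in sorted(rows_partners):
        detail.rows.append((
            gene, members[gene],
            tuple(sorted(rows_partners[gene])),
            tuple(sorted(rows_kinds[gene])),
        ))
    return detail


def pathway_cluster_graph(
    results: Sequence[EnrichmentResult], significance_cutoff: float = 0.05
) -> nx.Graph:
    """Undirected graph of enriched pathways weighted by Jaccard similarity
    of their contributing gene sets (edges only for Jaccard > 0)."""
    graph = nx.Graph()
    kept = [r for r in results if r.p_adj <= significance_cutoff]
    for r in kept:
        graph.add_node(r.pathway_id, name=r.pathway_name, p_adj=r.p_adj,
                       nease_score=r.nease_score)
    for i, r1 in enumerate(kept):
        g1 = set(r1.contributing_genes)
        for r2 in kept[i + 1:]:
            g2 = set(r2.contributing_genes)
            union = g1 | g2
            if not union:
                continue
            jaccard = len(g1 & g2) / len(union)
            if jaccard > 0.0:
                graph.add_edge(r1.pathway_id, r2.pathway_id, weight=jaccard)
    return graph


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [{
        "pathway_id": r.pathway_id, "name": r.pathway_name,
        "database": r.database_label, "N": r.n_population, "K": r.k_pathway,
        "n": r.n_affected, "k": r.k_affected, "p_raw": r.p_raw, "p_adj": r.p_adj,
        "nease_score": r.nease_score,
        "contributing_genes": ";".join(f"{g}:{c}" for g, c in r.contributing_genes.items()),
    } for r in results]
    return pd.DataFrame(rows, columns=[
        "pathway_id", "name", "database", "N", "K", "n", "k", "p_raw", "p_adj",
        "nease_score", "contributing_genes",
    ])


def export_cluster_graph(graph: nx.Graph, tsv_path: str | Path, json_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("pathway_a\tpathway_b\tjaccard\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.6g}\n")
    doc = nx.node_link_data(graph, edges="links")
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
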