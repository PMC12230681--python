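"""Internally consistent synthetic fixture bundles.

One call emits a toy genome (GTF), domain occurrences placed inside CDS
exons, multi-resource PPI tables generated from a planted ground-truth DDI
set plus uniform noise, pathway gene sets, and a protein-to-gene map — all
as plain-text files that round-trip through the package readers. A second
call plants splicing events on domain-bearing exons with a configurable
enrichment of one target pathway, plus sub-threshold decoys.

Everything is driven by one seeded generator, so a fixed seed yields a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_splice_events_bed
from .model import SpliceEvent, canonical_pair

__all__ = ["FixtureConfig", "SimulatedBundle", "simulate_interactome",
           "plant_splice_events"]

_EXON_LEN = 120  # nt, divisible by 3
_INTRON_LEN = 80
_GENE_GAP = 2000


@dataclass(frozen=True)
class FixtureConfig:
    n_genes: int = 20
    transcripts_per_gene: int = 2
    exons_per_transcript: int = 5
    n_domains: int = 15
    n_resources: int = 3
    n_ppi_edges: int = 40
    ppi_from_truth_fraction: float = 0.8
    noise_edge_fraction: float = 0.2
    n_truth_ddis: int = 10
    domains_per_protein: int = 1
    resource_coverage: float = 1.0
    n_pathways: int = 10
    pathway_size: int = 6
    target_pathway_enrichment_factor: float = 4.0
    n_events: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppi_from_truth_fraction", "noise_edge_fraction",
                     "resource_coverage"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_genes", "transcripts_per_gene", "exons_per_transcript",
                     "n_domains", "n_resources", "n_ppi_edges", "n_truth_ddis",
                     "domains_per_protein", "n_pathways", "pathway_size", "n_events"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pathway_size > self.n_genes:
            raise ValueError("pathway_size cannot exceed n_genes")
        if self.target_pathway_enrichment_factor < 1.0:
            raise ValueError("target_pathway_enrichment_factor must be >= 1")


@dataclass
class SimulatedBundle:
    """File paths plus construction bookkeeping for one fixture."""

    out_dir: Path
    config: FixtureConfig
    paths: dict[str, Path]
    #: gene -> list of (domain_id, genomic exon interval hosting it)
    gene_domain_exons: dict[str, list[tuple[str, tuple[int, int]]]]
    gene_meta: dict[str, tuple[str, str]]  # gene -> (chrom, strand)
    protein_of_gene: dict[str, str]
    pathways: dict[str, list[str]]
    truth_ddis: set[tuple[str, str]]
    edges: list[tuple[str, str]]

    @property
    def resource_names(self) -> list[str]:
        return sorted(k[4:] for k in self.paths if k.startswith("ppi_"))


def _gene_layout(cfg: FixtureConfig, i: int) -> tuple[str, str, list[tuple[int, int]]]:
    gene = f"g{i:03d}"
    strand = "+" if i % 2 == 0 else "-"
    start = 1 + i * (cfg.exons_per_transcript * (_EXON_LEN + _INTRON_LEN) + _GENE_GAP)
    exons = [(start + j * (_EXON_LEN + _INTRON_LEN),
              start + j * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN - 1)
             for j in range(cfg.exons_per_transcript)]
    return gene, strand, exons


def simulate_interactome(config: FixtureConfig, out_dir: str | Path) -> SimulatedBundle:
    """Write a complete fixture bundle into ``out_dir`` and return it."""
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aa_per_exon = _EXON_LEN // 3

    genes, gene_meta, gene_exons = [], {}, {}
    protein_of_gene = {}
    for i in range(config.n_genes):
        gene, strand, exons = _gene_layout(config, i)
        genes.append(gene)
        gene_meta[gene] = ("chr1", strand)
        gene_exons[gene] = exons
        protein_of_gene[gene] = f"P_{gene}"

    # --- GTF ---------------------------------------------------------------
    gtf_path = out_dir / "genome.gtf"
    with open(gtf_path, "w") as fh:
        for gene in genes:
            chrom, strand = gene_meta[gene]
            for t in range(config.transcripts_per_gene):
                tid = f"{gene}_t{t}"
                pid = protein_of_gene[gene]
                attrs = (f'gene_id "{gene}"; transcript_id "{tid}"; '
                         f'protein_id "{pid}";')
                for s, e in gene_exons[gene]:
                    fh.write(f"chr1\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")
                for s, e in gene_exons[gene]:
                    fh.write(f"chr1\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")

    # --- domain occurrences ------------------------------------------------
    domain_pool = [f"d{j:03d}" for j in range(config.n_domains)]
    gene_domain_exons: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    dom_path = out_dir / "domains.tsv"
    carriers: dict[str, list[str]] = {d: [] for d in domain_pool}
    with open(dom_path, "w") as fh:
        fh.write("protein_id\ttranscript_id\tdomain_id\taa_start\taa_end\n")
        for gene in genes:
            _chrom, strand = gene_meta[gene]
            exons = gene_exons[gene]
            n_dom = min(config.domains_per_protein, config.exons_per_transcript)
            dom_ids = rng.choice(len(domain_pool), size=n_dom, replace=False)
            exon_slots = rng.choice(config.exons_per_transcript, size=n_dom,
                                    replace=False)
            gene_domain_exons[gene] = []
            for d_idx, j in zip(dom_ids, exon_slots):
                dom = domain_pool[int(d_idx)]
                j = int(j)
                order_idx = j if strand == "+" else config.exons_per_transcript - 1 - j
                aa_start = order_idx * aa_per_exon + 3
                aa_end = order_idx * aa_per_exon + aa_per_exon - 3
                for t in range(config.transcripts_per_gene):
                    fh.write(f"{protein_of_gene[gene]}\t{gene}_t{t}\t{dom}"
                             f"\t{aa_start}\t{aa_end}\n")
                gene_domain_exons[gene].append((dom, exons[j]))
                carriers[dom].append(protein_of_gene[gene])

    # --- planted truth DDIs ------------------------------------------------
    occupied = sorted(d for d, ps in carriers.items() if ps)
    truth: set[tuple[str, str]] = set()
    attempts = 0
    while len(truth) < config.n_truth_ddis and attempts < 1000 * config.n_truth_ddis:
        attempts += 1
        a, b = (occupied[int(x)] for x in rng.integers(0, len(occupied), size=2))
        pair = canonical_pair(a, b)
        # require the pair to be realizable on two distinct proteins
        if pair[0] == pair[1] and len(carriers[pair[0]]) < 2:
            continue
        truth.add(pair)
    truth_path = out_dir / "truth_ddis.tsv"
    with open(truth_path, "w") as fh:
        fh.write("domain_a\tdomain_b\n")
        for a, b in sorted(truth):
            fh.write(f"{a}\t{b}\n")

    # --- PPI edges ---------------------------------------------------------
    n_truth_edges = round(config.n_ppi_edges * config.ppi_from_truth_fraction)
    n_noise_edges = round(config.n_ppi_edges * config.noise_edge_fraction)
    truth_list = sorted(truth)
    proteins = sorted(protein_of_gene.values())
    edges: set[tuple[str, str]] = set()

    attempts = 0
    while len(edges) < n_truth_edges and attempts < 500 * max(1, n_truth_edges):
        attempts += 1
        a, b = truth_list[int(rng.integers(0, len(truth_list)))]
        ca, cb = carriers[a], carriers[b]
        p = ca[int(rng.integers(0, len(ca)))]
        q = cb[int(rng.integers(0, len(cb)))]
        if p == q:
            continue
        edges.add(canonical_pair(p, q))
    n_from_truth = len(edges)
    attempts = 0
    while len(edges) < n_from_truth + n_noise_edges \
            and attempts < 500 * max(1, n_noise_edges):
        attempts += 1
        p, q = (proteins[int(x)] for x in rng.integers(0, len(proteins), size=2))
        if p == q:
            continue
        edges.add(canonical_pair(p, q))
    edge_list = sorted(edges)

    paths: dict[str, Path] = {
        "gtf": gtf_path, "domains": dom_path, "truth_ddis": truth_path,
    }
    for r in range(config.n_resources):
        name = f"res{r}"
        keep = [e for e in edge_list
                if rng.random() <= config.resource_coverage]
        if not keep:
            keep = [edge_list[0]]
        p = out_dir / f"ppi_{name}.tsv"
        with open(p, "w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in keep:
                fh.write(f"{a}\t{b}\n")
        paths[f"ppi_{name}"] = p

    # --- pathways and protein->gene map ------------------------------------
    # disjoint pathways when the gene universe allows it; otherwise
    # independent draws (overlap permitted)
    pathways: dict[str, list[str]] = {}
    if config.n_pathways * config.pathway_size <= config.n_genes:
        perm = rng.permutation(config.n_genes)
        for pw in range(config.n_pathways):
            chunk = perm[pw * config.pathway_size:(pw + 1) * config.pathway_size]
            pathways[f"pw{pw:02d}"] = sorted(genes[int(m)] for m in chunk)
    else:
        for pw in range(config.n_pathways):
            members = rng.choice(config.n_genes, size=config.pathway_size,
                                 replace=False)
            pathways[f"pw{pw:02d}"] = sorted(genes[int(m)] for m in members)
    gmt_path = out_dir / "pathways.gmt"
    with open(gmt_path, "w") as fh:
        for pid in sorted(pathways):
            fh.write("\t".join([pid, f"simulated pathway {pid}", *pathways[pid]]) + "\n")
    paths["gmt"] = gmt_path

    map_path = out_dir / "protein_gene_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("protein_id\tgene_id\n")
        for gene in genes:
            fh.write(f"{protein_of_gene[gene]}\t{gene}\n")
    paths["protein_gene_map"] = map_path

    manifest = {
        "config": dataclasses.asdict(config),
        "files": sorted(str(p.name) for p in paths.values()),
        "n_truth_edges_realized": n_from_truth,
        "n_edges": len(edge_list),
    }
    manifest_path = out_dir / "fixture_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = manifest_path

    return SimulatedBundle(
        out_dir=out_dir, config=config, paths=paths,
        gene_domain_exons=gene_domain_exons, gene_meta=gene_meta,
        protein_of_gene=protein_of_gene, pathways=pathways, truth_ddis=truth,
        edges=edge_list,
    )


def _annotated_edges(bundle: SimulatedBundle) -> dict[tuple[str, str], list[tuple[str, str]]]:
    """Edges annotatable by the planted truth, with their mediating domain
    pairs as (domain on endpoint A's gene, domain on endpoint B's gene)."""
    gene_of = {p: g for g, p in bundle.protein_of_gene.items()}
    out = {}
    for p, q in bundle.edges:
        doms_p = [d for d, _iv in bundle.gene_domain_exons.get(gene_of[p], [])]
        doms_q = [d for d, _iv in bundle.gene_domain_exons.get(gene_of[q], [])]
        pairs = [(a, b) for a in doms_p for b in doms_q
                 if canonical_pair(a, b) in bundle.truth_ddis]
        if pairs:
            out[(p, q)] = pairs
    return out


def plant_splice_events(
    bundle: SimulatedBundle,
    target_pathway: str,
    config: FixtureConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Plant significant events on domain-bearing exons, plus decoys.

    Each significant event targets one truth-annotated edge: the edge is
    drawn with weight ``target_pathway_enrichment_factor`` when incident to
    ``target_pathway`` (factor 1 reduces to uniform edge sampling, i.e. the
    null), then one mediating domain on one endpoint is disrupted by an
    event on its host exon. Significant events carry |delta_psi| = 0.2
    (2x the default threshold) and significance 5e-4; an equal number of
    sub-threshold decoy events is added. Returns the events file path.
    """
    config = config or bundle.config
    if target_pathway not in bundle.pathways:
        raise KeyError(f"unknown pathway {target_pathway!r}")
    rng = np.random.default_rng(bundle.config.seed + 1 if seed is None else seed)

    candidates = sorted(g for g, doms in bundle.gene_domain_exons.items() if doms)
    target_genes = set(bundle.pathways[target_pathway])
    if not target_genes & set(candidates):
        raise ValueError(f"pathway {target_pathway!r} has no domain-bearing genes")
    annotated = _annotated_edges(bundle)
    if not annotated:
        raise ValueError("fixture has no truth-annotated edges to disrupt")
    gene_of = {p: g for g, p in bundle.protein_of_gene.items()}
    edge_keys = sorted(annotated)
    weights = np.array([
        config.target_pathway_enrichment_factor
        if {gene_of[p], gene_of[q]} & target_genes else 1.0
        for p, q in edge_keys
    ])
    weights = weights / weights.sum()

    exon_of_domain = {
        (g, d): iv for g, doms in bundle.gene_domain_exons.items() for d, iv in doms
    }
    # collateral[(gene, domain)] = edges whose evidence cites that pair; used
    # to pick the most surgical disruption for each planted event
    collateral: dict[tuple[str, str], int] = {}
    for (p, q), pairs in annotated.items():
        for dom_a, dom_b in set(pairs):
            collateral[(gene_of[p], dom_a)] = collateral.get((gene_of[p], dom_a), 0) + 1
            collateral[(gene_of[q], dom_b)] = collateral.get((gene_of[q], dom_b), 0) + 1

    events: list[SpliceEvent] = []
    picks = rng.choice(len(edge_keys), size=config.n_events, p=weights)
    for pick in picks:
        p, q = edge_keys[int(pick)]
        choices = sorted({
            (gene, dom)
            for dom_a, dom_b in annotated[(p, q)]
            for gene, dom in ((gene_of[p], dom_a), (gene_of[q], dom_b))
        })
        if config.target_pathway_enrichment_factor > 1.0:
            # bias the disruption to the target-side endpoint so collateral
            # losses also land on pathway-incident edges
            on_target = [c for c in choices if c[0] in target_genes]
            choices = on_target or choices
        min_coll = min(collateral[c] for c in choices)
        best = [c for c in choices if collateral[c] == min_coll]
        gene, dom = best[int(rng.integers(0, len(best)))]
        s, e = exon_of_domain[(gene, dom)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        chrom, strand = bundle.gene_meta[gene]
        events.append(SpliceEvent(
            gene_id=gene, chrom=chrom, strand=strand, exon_start=s, exon_end=e,
            delta_psi=sign * 0.2, significance=5e-4, dialect="generic_bed",
        ))
    # decoys: below both thresholds, placed uniformly
    decoy_picks = rng.integers(0, len(candidates), size=config.n_events)
    for pick in decoy_picks:
        gene = candidates[int(pick)]
        dom, (s, e) = bundle.gene_domain_exons[gene][0]
        chrom, strand = bundle.gene_meta[gene]
        events.append(SpliceEvent(
            gene_id=gene, chrom=chrom, strand=strand, exon_start=s, exon_end=e,
            delta_psi=0.01, significance=0.8, dialect="generic_bed",
        ))

    events_path = bundle.out_dir / "events.bed"
    write_splice_events_bed(events, events_path)
    bundle.paths["events"] = events_path
    return events_path
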