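# splicenet

Splicing-aware joint PPI/DDI network analysis: build a protein–protein
interaction network annotated with domain-level evidence, predict
domain–domain interactions (DDIs) from multi-resource PPI co-occurrence, map
differential exon-skipping events onto protein domains/motifs/residues via
genomic coordinates, and run edge-level hypergeometric pathway enrichment
over the rewired interactions.

## Modules

| Module | Purpose |
| --- | --- |
| `splicenet.io` | Readers/writers: PPI TSVs, GTF transcript models, splice-event dialects (rMATS SE, Whippet, MAJIQ-style, generic BED), GMT gene sets, evidence tables, result TSVs |
| `splicenet.network` | Joint PPI/DDI network construction, isoform-level evidence views, on-the-fly network characteristics (N, per-pathway K) |
| `splicenet.ddi` | Cosine co-occurrence DDI scoring, reliability-weighted score combination, F1 threshold calibration, gold/silver/bronze tiers, seeded random weight search |
| `splicenet.mapping` | Event filtering (deltaPSI / significance), protein↔genomic coordinate lifting, event→feature mapping, affected-edge derivation |
| `splicenet.enrichment` | Edge-level hypergeometric test, Benjamini–Hochberg correction, ranking score, per-pathway detail, pathway cluster graph |
| `splicenet.simulate` | Self-consistent synthetic fixture bundles with planted DDI ground truth and planted pathway enrichment signal |
| `splicenet.cli` / `splicenet.pipeline` | Orchestration and the `splicenet` command-line tool |

Coordinates are 1-based inclusive internally (GTF convention); 0-based
inputs (rMATS `exonStart_0base`, BED starts) are converted on read.

## CLI

```bash
# write a synthetic fixture bundle with a planted signal on pathway pw00
splicenet simulate --out-dir bundle --seed 0

# full pipeline: build -> filter -> map -> derive -> enrich
splicenet run \
    --gtf bundle/genome.gtf --domains bundle/domains.tsv \
    --ppi res0=bundle/ppi_res0.tsv --ppi res1=bundle/ppi_res1.tsv \
    --ppi res2=bundle/ppi_res2.tsv \
    --ddi-templates bundle/truth_ddis.tsv \
    --events bundle/events.bed --gene-sets bundle/pathways.gmt \
    --protein-gene-map bundle/protein_gene_map.tsv \
    --out-dir out
```

Other subcommands: `build` (network only), `predict-ddi` (DDI scoring,
calibration and weight search), `map-events` (event→feature mapping only),
`enrich` (re-run enrichment from exported tables). Event thresholds default
to |deltaPSI| ≥ 0.05 and significance ≤ 0.05; predicted DDIs are included
via `--tier-filter gold`, `gold,silver`, or `gold,silver,bronze`.

Outputs per run: `enrichment.tsv`, `affected_features.tsv`,
`affected_edges.tsv`, `pathway_detail_<id>.tsv`, `network.json`,
`edge_evidence.tsv`, `pathway_clusters.{tsv,json}`, `manifest.json`, and a
deterministic `run_metadata.json` with stage counts.

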