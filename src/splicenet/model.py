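"""Core data model shared across the pipeline.

Coordinate conventions: all genomic coordinates are 1-based inclusive
(GTF-style); 0-based inputs are converted on read. Protein (amino-acid)
coordinates are 1-based inclusive. PPI edges are unordered and stored
with endpoints in lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PPIEdgeRecord",
    "TranscriptModel",
    "SpliceEvent",
    "PathwayGeneSet",
    "DomainOccurrence",
    "EvidenceItem",
    "AnnotatedEdge",
    "JointNetwork",
    "NetworkStats",
    "DDIScoreRecord",
    "CalibrationResult",
    "AffectedFeatures",
    "AffectedEdgeSet",
    "EnrichmentResult",
    "PathwayDetail",
    "canonical_pair",
    "DDI_EXPERIMENTAL",
    "DDI_PREDICTED",
    "DMI",
    "RESIDUE",
    "TIERS",
]

DDI_EXPERIMENTAL = "ddi_experimental"
DDI_PREDICTED = "ddi_predicted"
DMI = "dmi"
RESIDUE = "residue"

#: confidence tiers for predicted domain-domain interactions, strongest first
TIERS = ("gold", "silver", "bronze")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPIEdgeRecord:
    """One protein-protein interaction from one resource.

    Endpoints are stored in canonical order; ``is_homodimer`` flags
    self-interactions.
    """

    protein_a: str
    protein_b: str
    resource: str

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("PPI endpoints must be non-empty")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    @property
    def is_homodimer(self) -> bool:
        return self.protein_a == self.protein_b

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are tuples of (start, end) genomic intervals,
    1-based inclusive, non-overlapping, sorted by genomic start regardless
    of strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        for name, ivals in (("exons", self.exons), ("cds", self.cds)):
            prev_end = 0
            for s, e in ivals:
                if s > e:
                    raise ValueError(f"{name} interval ({s}, {e}) reversed")
                if s <= prev_end:
                    raise ValueError(f"{name} intervals overlap or unsorted")
                prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3


@dataclass(frozen=True)
class SpliceEvent:
    """One differential exon-skipping event, normalized to 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    delta_psi: float
    significance: float
    dialect: str

    def __post_init__(self) -> None:
        if self.exon_start > self.exon_end:
            raise ValueError("exon_start > exon_end")
        if not -1.0 <= self.delta_psi <= 1.0:
            raise ValueError(f"delta_psi {self.delta_psi} outside [-1, 1]")
        if not 0.0 <= self.significance <= 1.0:
            raise ValueError(f"significance {self.significance} outside [0, 1]")

    @property
    def event_id(self) -> str:
        return f"{self.gene_id}:{self.chrom}:{self.exon_start}-{self.exon_end}"

    def direction(self, condition_labels: tuple[str, str] = ("A", "B")) -> str:
        """Sign convention: delta_psi = PSI(B) - PSI(A); negative means the
        exon is lost in condition B."""
        lost_in = condition_labels[1] if self.delta_psi < 0 else condition_labels[0]
        return f"exon-loss in condition {lost_in}"


@dataclass(frozen=True)
class PathwayGeneSet:
    pathway_id: str
    pathway_name: str
    database_label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id} has no genes")


@dataclass(frozen=True)
class DomainOccurrence:
    """One domain instance on one protein/transcript.

    ``genomic_footprint`` is derived by lifting the amino-acid interval
    through the transcript CDS; empty when the transcript has no usable CDS.
    """

    protein_id: str
    transcript_id: str
    domain_id: str
    aa_start: int
    aa_end: int
    genomic_footprint: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise ValueError("require 1 <= aa_start <= aa_end")

    def with_footprint(self, footprint: tuple[tuple[int, int], ...]) -> "DomainOccurrence":
        return replace(self, genomic_footprint=footprint)


@dataclass(frozen=True)
class EvidenceItem:
    """Domain-level support for one annotated PPI edge.

    Orientation is relative to the canonical edge (protein_a <= protein_b):
    for DDI kinds, ``domain_a`` sits on protein_a and ``domain_b`` on
    protein_b. For DMI, the interacting domain sits on the endpoint given by
    ``domain_on_a`` and the motif span on the other endpoint. Residue
    evidence carries >= 1 interface position per endpoint.
    """

    kind: str
    domain_a: str | None = None
    domain_b: str | None = None
    motif_span: tuple[int, int] | None = None
    domain_on_a: bool = True
    residue_positions_a: tuple[int, ...] = ()
    residue_positions_b: tuple[int, ...] = ()
    tier: str = "n/a"

    def __post_init__(self) -> None:
        if self.kind in (DDI_EXPERIMENTAL, DDI_PREDICTED):
            if self.domain_a is None or self.domain_b is None:
                raise ValueError("DDI evidence requires two domain ids")
        elif self.kind == DMI:
            if self.domain_a is None or self.motif_span is None:
                raise ValueError("DMI evidence requires a domain and a motif span")
        elif self.kind == RESIDUE:
            if not self.residue_positions_a or not self.residue_positions_b:
                raise ValueError("residue evidence requires positions on both endpoints")
        else:
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        if self.kind == DDI_PREDICTED and self.tier not in TIERS:
            raise ValueError(f"predicted DDI requires a tier, got {self.tier!r}")


@dataclass(frozen=True)
class AnnotatedEdge:
    """A PPI edge together with its domain-level supporting evidence."""

    protein_a: str
    protein_b: str
    evidence: tuple[EvidenceItem, ...]

    def __post_init__(self) -> None:
        if self.protein_a > self.protein_b:
            raise ValueError("edge endpoints not canonical")
        if not self.evidence:
            raise ValueError("annotated edge requires >= 1 evidence item")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass
class JointNetwork:
    """PPI network with domain-level edge annotation.

    ``edges`` holds annotated edges only; PPIs without any attaching
    evidence are kept in ``unannotated_edges`` so the two partitions always
    sum to the distinct input PPI pairs.
    """

    proteins: set[str]
    edges: dict[tuple[str, str], AnnotatedEdge]
    unannotated_edges: set[tuple[str, str]]
    domains_by_protein: dict[str, frozenset[str]]
    transcript_to_protein: dict[str, str]
    provenance: dict
    skipped_records: int = 0

    @property
    def n_annotated(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class NetworkStats:
    """On-the-fly network characteristics for the edge-level test."""

    n_edges_annotated: int
    n_proteins: int
    k_per_pathway: dict[str, int] = field(hash=False, compare=False, default_factory=dict)
    unmapped_proteins: int = 0


@dataclass
class DDIScoreRecord:
    """One candidate domain pair with per-resource and combined scores."""

    domain_a: str
    domain_b: str
    per_resource: dict[str, float]
    combined: float
    n_supporting_resources: int
    tier: str = "below"

    def __post_init__(self) -> None:
        if self.domain_a > self.domain_b:
            raise ValueError("domain pair not canonical")

    @property
    def key(self) -> tuple[str, str]:
        return (self.domain_a, self.domain_b)


@dataclass(frozen=True)
class CalibrationResult:
    threshold: float
    precision: float
    recall: float
    f1: float
    #: rows of (threshold, precision, recall, f1) over all candidate thresholds
    curve: tuple[tuple[float, float, float, float], ...] = ()


@dataclass
class AffectedFeatures:
    """Protein features hit by one splice event (genomic overlap >= 1 nt)."""

    event: SpliceEvent
    transcripts: list[str] = field(default_factory=list)
    #: (occurrence, overlap in nt with the event exon)
    domains: list[tuple[DomainOccurrence, int]] = field(default_factory=list)
    #: (protein_id, transcript_id, motif_start, motif_end, overlap_nt)
    motifs: list[tuple[str, str, int, int, int]] = field(default_factory=list)
    #: (protein_id, transcript_id, residue_position, overlap_nt)
    residues: list[tuple[str, str, int, int]] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    unmapped: bool = False

    @property
    def is_empty(self) -> bool:
        return not (self.domains or self.motifs or self.residues)


@dataclass
class AffectedEdgeSet:
    """Annotated edges losing >= 1 evidence item due to splice events."""

    #: edge key -> (lost evidence items, surviving evidence items)
    edges: dict[tuple[str, str], tuple[tuple[EvidenceItem, ...], tuple[EvidenceItem, ...]]]
    #: edge key -> originating event ids
    events_by_edge: dict[tuple[str, str], tuple[str, ...]]

    @property
    def n(self) -> int:
        return len(self.edges)


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    database_label: str
    n_population: int  # N: annotated edges in the network
    k_pathway: int  # K: annotated edges incident to the pathway
    n_affected: int  # n: affected edges
    k_affected: int  # k: affected edges incident to the pathway
    p_raw: float
    p_adj: float = float("nan")
    nease_score: float = float("nan")
    #: gene -> number of affected incident edges it contributes
    contributing_genes: dict[str, int] = field(default_factory=dict)


@dataclass
class PathwayDetail:
    pathway_id: str
    #: rows of (gene, is_member, partner genes inside pathway, lost evidence kinds)
    rows: list[tuple[str, bool, tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)
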