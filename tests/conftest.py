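import numpy as np
import pytest

from splicenet.model import TranscriptModel


@pytest.fixture
def plus_transcript():
    """Two-exon plus-strand transcript, exons (101-160), (201-230), CDS identical."""
    return TranscriptModel(
        transcript_id="t_plus", gene_id="gX", chrom="chr1", strand="+",
        exons=((101, 160), (201, 230)), cds=((101, 160), (201, 230)),
        protein_id="pX",
    )


@pytest.fixture
def minus_transcript():
    """Minus-strand transcript; CDS exons (201-230), (101-160) in transcription order."""
    return TranscriptModel(
        transcript_id="t_minus", gene_id="gY", chrom="chr1", strand="-",
        exons=((101, 160), (201, 230)), cds=((101, 160), (201, 230)),
        protein_id="pY",
    )


def random_transcript(rng: np.random.Generator) -> TranscriptModel:
    """Random coding transcript (CDS length divisible by 3, both strands)."""
    n_exons = int(rng.integers(1, 6))
    n_aa = int(rng.integers(n_exons, 40))
    # split 3*n_aa coding nt over exons, each >= 1 nt
    cuts = np.sort(rng.choice(np.arange(1, 3 * n_aa), size=n_exons - 1, replace=False))
    lengths = np.diff(np.concatenate(([0], cuts, [3 * n_aa])))
    pos = int(rng.integers(1, 1000))
    cds = []
    for length in lengths:
        cds.append((pos, pos + int(length) - 1))
        pos += int(length) + int(rng.integers(1, 100))  # intron gap >= 1
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(
        transcript_id="t_rand", gene_id="g_rand", chrom="chr1", strand=strand,
        exons=tuple(cds), cds=tuple(cds), protein_id="p_rand",
    )
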