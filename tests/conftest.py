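"""Shared fixtures: a small hand-built annotation and generator configs."""

from __future__ import annotations

import numpy as np
import pytest

from exonpipe.annotation import GenomeAnnotation, annotation_from_string
from exonpipe.simulate import SimulationConfig

_BASES = "ACGT"


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def gtf_line(chrom, feature, start0, end, strand, gene, tx, exon) -> str:
    """One GTF row from 0-based half-open coordinates."""
    attrs = f'gene_id "{gene}"; transcript_id "{tx}"; exon_id "{exon}";'
    return f"{chrom}\ttest\t{feature}\t{start0 + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"


# Toy annotation: 2 genes / 3 transcripts / 7 exons on one 600-nt chromosome.
#
# gene GA (+): E1 (10,45) 35 nt, E2 (100,161) 61 nt, E3 (200,245) 45 nt
#   TA1 = E1-E2-E3, CDS 141 nt (frame-consistent; E1 end phase 2, E2 end 0)
#   TA2 = E1-E3,    CDS  80 nt (NOT a multiple of 3 -> frame-inconsistent)
# gene GB (-): E4..E7, lengths 36/60/45/36 (all multiples of 3, phases all 0)
#   TB1 = E4-E5-E6-E7 in transcription order (descending coordinates)
GENOME_LEN = 600


@pytest.fixture(scope="session")
def toy_gtf() -> str:
    rows = []
    ga = [("E1", 10, 45), ("E2", 100, 161), ("E3", 200, 245)]
    for tx, exons in (("TA1", ["E1", "E2", "E3"]), ("TA2", ["E1", "E3"])):
        for name, s, e in ga:
            if name in exons:
                rows.append(gtf_line("chr1", "exon", s, e, "+", "GA", tx, name))
                rows.append(gtf_line("chr1", "CDS", s, e, "+", "GA", tx, name))
    # minus-strand gene: genomic order E7..E4 reversed = transcription order
    gb = [("E7", 300, 336), ("E6", 360, 420), ("E5", 450, 495), ("E4", 520, 556)]
    for name, s, e in gb:
        rows.append(gtf_line("chr1", "exon", s, e, "-", "GB", "TB1", name))
        rows.append(gtf_line("chr1", "CDS", s, e, "-", "GB", "TB1", name))
    return "".join(rows)


@pytest.fixture(scope="session")
def toy_genome() -> str:
    seq = random_sequence(GENOME_LEN, seed=42)
    return f">chr1\n{seq}\n"


@pytest.fixture(scope="session")
def toy_annotation(toy_gtf, toy_genome) -> GenomeAnnotation:
    return annotation_from_string(toy_gtf, toy_genome)


@pytest.fixture()
def small_config() -> SimulationConfig:
    """A fast cohort: 3 pairs, 12 genes, 3k reads per sample."""
    return SimulationConfig(
        seed=7, n_pairs=3, n_genes=12, reads_per_sample=3000,
        n_novel_skip=1, n_pattern2=1, n_pattern3=1, deg_fraction=0.25,
    )
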