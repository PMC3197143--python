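"""Genome annotation model: genes, transcripts, exons and coding phases.

Internal coordinates are 0-based half-open throughout; conversion from the
GTF convention (1-based, inclusive) happens only at the file boundary.

The *phase* of a coding exon boundary is the position within a codon at
which the exon starts or ends: phase 0 means the boundary coincides with a
codon boundary, phase 1 falls between the first and second base of a codon,
and phase 2 between the second and third.  Two exons whose donor end phase
equals the acceptor start phase can be joined without a frame shift, which
is the condition used downstream to enumerate candidate novel junctions.
Phases are defined only for coding exons; UTR-only exons carry ``None``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

_GTF_UNDEF = "."


@dataclass
class ExonRecord:
    """A deduplicated genomic exon (one record per (chrom, start, end, strand))."""

    exon_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    transcript_ids: set[str] = field(default_factory=set)
    coding: bool = False
    start_phase: int | None = None
    end_phase: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"exon {self.exon_id}: start must be < end, got ({self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"exon {self.exon_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class TranscriptModel:
    """One transcript: ordered exons (transcription order) plus CDS spans.

    ``cds_spans`` maps exon_id to the genomic (start, end) of the coding part
    of that exon within this transcript; exons absent from the map are
    non-coding in this transcript.  ``exon_phases`` maps exon_id to
    (start_phase, end_phase) of the coding part, filled in by
    :func:`compute_exon_phases`.
    """

    transcript_id: str
    gene_id: str
    exons: list[ExonRecord] = field(default_factory=list)
    cds_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    exon_phases: dict[str, tuple[int, int]] = field(default_factory=dict)
    frame_consistent: bool = True

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def cdna_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_spans.values())

    def coding_exons(self) -> list[ExonRecord]:
        """Exons carrying CDS in this transcript, in transcription order."""
        return [e for e in self.exons if e.exon_id in self.cds_spans]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcript_ids: list[str] = field(default_factory=list)


class GenomeAnnotation:
    """Cross-indexed annotation plus a genome sequence accessor."""

    def __init__(self, genome: dict[str, str] | None = None) -> None:
        self.genes: dict[str, GeneModel] = {}
        self.transcripts: dict[str, TranscriptModel] = {}
        self.exons: dict[str, ExonRecord] = {}
        self._exons_by_key: dict[tuple[str, int, int, str], ExonRecord] = {}
        self.genome: dict[str, str] = genome or {}

    # -- construction -----------------------------------------------------

    def add_exon(
        self,
        gene_id: str,
        transcript_id: str,
        chrom: str,
        start: int,
        end: int,
        strand: str,
        exon_id: str | None = None,
    ) -> ExonRecord:
        """Register an exon occurrence, deduplicating by genomic coordinates."""
        key = (chrom, start, end, strand)
        rec = self._exons_by_key.get(key)
        if rec is None:
            eid = exon_id or f"E:{chrom}:{start + 1}-{end}:{strand}"
            rec = ExonRecord(eid, gene_id, chrom, start, end, strand)
            self._exons_by_key[key] = rec
            self.exons[rec.exon_id] = rec
        rec.transcript_ids.add(transcript_id)
        return rec

    # -- accessors --------------------------------------------------------

    def exons_of_gene(self, gene_id: str) -> list[ExonRecord]:
        """All distinct exons of a gene, in transcription order."""
        gene = self.genes[gene_id]
        seen: dict[str, ExonRecord] = {}
        for tid in gene.transcript_ids:
            for e in self.transcripts[tid].exons:
                seen[e.exon_id] = e
        reverse = gene.strand == "-"
        return sorted(seen.values(), key=lambda e: e.start, reverse=reverse)

    def extract_sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Genomic subsequence on the requested strand (0-based half-open)."""
        if chrom not in self.genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.genome[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval ({start}, {end}) out of bounds for {chrom} (length {len(seq)})"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub

    def transcript_cdna(self, transcript_id: str) -> str:
        """Spliced transcript sequence, exons concatenated in transcription order."""
        tx = self.transcripts[transcript_id]
        return "".join(
            self.extract_sequence(e.chrom, e.start, e.end, e.strand) for e in tx.exons
        )

    def summary(self) -> dict[str, int]:
        return {
            "genes": len(self.genes),
            "transcripts": len(self.transcripts),
            "exons": len(self.exons),
        }

    # -- output -----------------------------------------------------------

    def to_gtf(self, handle: IO[str]) -> None:
        """Write the model back out as GTF (1-based inclusive coordinates)."""
        for gene_id in sorted(self.genes):
            gene = self.genes[gene_id]
            for tid in sorted(gene.transcript_ids):
                tx = self.transcripts[tid]
                for e in tx.exons:
                    attrs = (
                        f'gene_id "{gene_id}"; transcript_id "{tid}"; '
                        f'exon_id "{e.exon_id}";'
                    )
                    handle.write(
                        f"{e.chrom}\texonpipe\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )
                    span = tx.cds_spans.get(e.exon_id)
                    if span is not None:
                        handle.write(
                            f"{e.chrom}\texonpipe\tCDS\t{span[0] + 1}\t{span[1]}\t.\t"
                            f"{e.strand}\t.\t{attrs}\n"
                        )

    def summary_tsv(self, handle: IO[str]) -> None:
        handle.write("gene_id\tchrom\tstrand\tn_transcripts\tn_exons\n")
        for gene_id in sorted(self.genes):
            g = self.genes[gene_id]
            handle.write(
                f"{gene_id}\t{g.chrom}\t{g.strand}\t{len(g.transcript_ids)}\t"
                f"{len(self.exons_of_gene(gene_id))}\n"
            )


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(
    gtf_stream: IO[str] | Iterable[str], genome_fasta: IO[str] | str | None
) -> GenomeAnnotation:
    """Parse a GTF plus genome FASTA into a cross-indexed :class:`GenomeAnnotation`.

    Coordinates are converted from GTF 1-based inclusive to internal 0-based
    half-open.  CDS features falling outside their exon's bounds are rejected
    with a logged warning; a transcript with no exon features is an error.
    Exon phases are computed for every transcript that carries CDS features.
    """
    genome: dict[str, str] = {}
    if genome_fasta is not None:
        if isinstance(genome_fasta, str):
            with open(genome_fasta) as fh:
                genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
        else:
            genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(genome_fasta, "fasta")}

    ann = GenomeAnnotation(genome)
    # exon rows per transcript, and CDS rows to attach after exons exist
    tx_meta: dict[str, str] = {}  # transcript_id -> gene_id
    tx_exons: dict[str, list[tuple[int, str, str, int, int, str, str | None]]] = {}
    cds_rows: list[tuple[str, str, int, int]] = []  # transcript, chrom, start, end

    for line in gtf_stream:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF line: {line!r}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
        if feature not in ("exon", "CDS"):
            continue
        start = int(start_s) - 1  # to 0-based half-open
        end = int(end_s)
        attrs = _parse_gtf_attributes(attr_s)
        gene_id = attrs.get("gene_id")
        transcript_id = attrs.get("transcript_id")
        if gene_id is None or transcript_id is None:
            raise ValueError(f"GTF record missing gene_id/transcript_id: {line!r}")
        tx_meta.setdefault(transcript_id, gene_id)
        if feature == "exon":
            order = len(tx_exons.setdefault(transcript_id, []))
            tx_exons[transcript_id].append(
                (order, gene_id, chrom, start, end, strand, attrs.get("exon_id"))
            )
        else:
            cds_rows.append((transcript_id, chrom, start, end))

    for transcript_id, gene_id in tx_meta.items():
        rows = tx_exons.get(transcript_id)
        if not rows:
            raise ValueError(f"transcript {transcript_id} has no exon features")
        tx = TranscriptModel(transcript_id, gene_id)
        chrom = rows[0][2]
        strand = rows[0][5]
        # transcription order: ascending genomic start on +, descending on -
        rows_sorted = sorted(rows, key=lambda r: r[3], reverse=(strand == "-"))
        for _order, _g, r_chrom, start, end, r_strand, exon_id in rows_sorted:
            rec = ann.add_exon(gene_id, transcript_id, r_chrom, start, end, r_strand, exon_id)
            tx.exons.append(rec)
        ann.transcripts[transcript_id] = tx
        gene = ann.genes.setdefault(gene_id, GeneModel(gene_id, chrom, strand))
        gene.transcript_ids.append(transcript_id)

    for transcript_id, chrom, start, end in cds_rows:
        tx = ann.transcripts.get(transcript_id)
        if tx is None:
            logger.warning("CDS for unknown transcript %s skipped", transcript_id)
            continue
        host = next(
            (e for e in tx.exons if e.chrom == chrom and e.start <= start and end <= e.end),
            None,
        )
        if host is None:
            logger.warning(
                "CDS (%s:%d-%d) outside exon bounds of transcript %s; record rejected",
                chrom, start + 1, end, transcript_id,
            )
            continue
        tx.cds_spans[host.exon_id] = (start, end)
        host.coding = True

    for tx in ann.transcripts.values():
        if tx.cds_spans:
            compute_exon_phases(tx)
    _assign_exon_phases(ann)

    s = ann.summary()
    logger.info(
        "loaded annotation: %d genes, %d transcripts, %d exons",
        s["genes"], s["transcripts"], s["exons"],
    )
    return ann


def compute_exon_phases(transcript: TranscriptModel) -> dict[str, tuple[int, int]]:
    """Assign start/end phases to the coding exons of one transcript.

    The first coding exon starts at phase 0; each exon's end phase is the
    cumulative CDS length so far modulo 3, and the next coding exon starts
    at the previous end phase.  A transcript whose total CDS length is not a
    multiple of 3 is flagged frame-inconsistent and keeps no phases, which
    excludes it from phase-based junction pairing downstream.
    """
    if not transcript.cds_spans:
        raise ValueError(f"transcript {transcript.transcript_id} has no CDS")
    phases: dict[str, tuple[int, int]] = {}
    cumulative = 0
    for exon in transcript.coding_exons():
        start, end = transcript.cds_spans[exon.exon_id]
        start_phase = cumulative % 3
        cumulative += end - start
        phases[exon.exon_id] = (start_phase, cumulative % 3)
    if cumulative % 3 != 0:
        transcript.frame_consistent = False
        transcript.exon_phases = {}
        logger.warning(
            "transcript %s: CDS length %d not a multiple of 3; flagged frame-inconsistent",
            transcript.transcript_id, cumulative,
        )
        return {}
    transcript.frame_consistent = True
    transcript.exon_phases = phases
    return phases


def _assign_exon_phases(ann: GenomeAnnotation) -> None:
    """Propagate per-transcript phases onto shared exon records.

    When several frame-consistent transcripts assign phases to the same
    genomic exon the first transcript in sorted id order wins; synthetic
    annotations built by this package always agree across transcripts.
    """
    for tid in sorted(ann.transcripts):
        tx = ann.transcripts[tid]
        if not tx.frame_consistent:
            continue
        for exon_id, (sp, ep) in tx.exon_phases.items():
            exon = ann.exons[exon_id]
            if exon.start_phase is None:
                exon.start_phase = sp
                exon.end_phase = ep


def annotation_from_string(gtf_text: str, fasta_text: str | None = None) -> GenomeAnnotation:
    """Convenience loader for tests and small fixtures."""
    fasta = StringIO(fasta_text) if fasta_text is not None else None
    return load_annotation(StringIO(gtf_text), fasta)
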