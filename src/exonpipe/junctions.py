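"""Known and novel exon-exon junction reference construction and detection.

A junction reference sequence is the donor exon's 3' flank concatenated
with the acceptor exon's 5' flank, each flank ``L - min_overhang`` nt long
(28 for 36-nt reads and the 8-base overhang rule), truncated to the exon
length when the exon is shorter.  A read supports a junction only when it
covers at least ``min_overhang`` nt on *both* sides of the junction point.

Known junctions are the exon adjacencies present in annotated transcripts,
deduplicated across transcripts.  Novel candidates are unannotated ordered
within-gene pairs of coding exons whose reading-frame phases are
compatible: the donor's end phase equals the acceptor's start phase, so
joining them preserves the reading frame (the condition met by in-frame
exon-skipping isoforms).  UTR-only and phase-undefined exons never pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from exonpipe.align import DEFAULT_READ_LENGTH, HitTable
from exonpipe.annotation import ExonRecord, GenomeAnnotation

DEFAULT_MIN_OVERHANG = 8


@dataclass
class JunctionRecord:
    """One exon-exon junction reference sequence."""

    junction_id: str
    gene_id: str
    donor_exon: str
    acceptor_exon: str
    donor_end_phase: int | None
    acceptor_start_phase: int | None
    left_flank: int
    right_flank: int
    sequence: str
    status: str  # "known" | "novel-candidate"

    def __post_init__(self) -> None:
        if len(self.sequence) != self.left_flank + self.right_flank:
            raise ValueError(
                f"junction {self.junction_id}: sequence length "
                f"{len(self.sequence)} != {self.left_flank} + {self.right_flank}"
            )


@dataclass
class JunctionReference:
    """An ordered collection of junction records, indexable by id."""

    records: list[JunctionRecord]

    def __post_init__(self) -> None:
        self._by_id = {r.junction_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate junction ids")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, junction_id: str) -> JunctionRecord:
        return self._by_id[junction_id]

    def __contains__(self, junction_id: str) -> bool:
        return junction_id in self._by_id

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.donor_exon, r.acceptor_exon) for r in self.records}

    def as_references(self) -> list[tuple[str, str]]:
        """(id, sequence) pairs for the aligner."""
        return [(r.junction_id, r.sequence) for r in self.records]

    def to_fasta(self, handle: IO[str]) -> None:
        for r in self.records:
            handle.write(
                f">{r.junction_id} gene={r.gene_id} donor={r.donor_exon} "
                f"acceptor={r.acceptor_exon} status={r.status}\n{r.sequence}\n"
            )

    def to_tsv(self, handle: IO[str]) -> None:
        handle.write(
            "junction_id\tgene_id\tdonor_exon\tacceptor_exon\t"
            "donor_end_phase\tacceptor_start_phase\tleft_flank\tright_flank\tstatus\n"
        )
        for r in self.records:
            handle.write(
                f"{r.junction_id}\t{r.gene_id}\t{r.donor_exon}\t{r.acceptor_exon}\t"
                f"{r.donor_end_phase}\t{r.acceptor_start_phase}\t"
                f"{r.left_flank}\t{r.right_flank}\t{r.status}\n"
            )


def _donor_flank(ann: GenomeAnnotation, exon: ExonRecord, flank: int) -> str:
    """Last ``flank`` nt of the exon in transcription orientation."""
    flank = min(flank, exon.length)
    if exon.strand == "+":
        return ann.extract_sequence(exon.chrom, exon.end - flank, exon.end, "+")
    return ann.extract_sequence(exon.chrom, exon.start, exon.start + flank, "-")


def _acceptor_flank(ann: GenomeAnnotation, exon: ExonRecord, flank: int) -> str:
    """First ``flank`` nt of the exon in transcription orientation."""
    flank = min(flank, exon.length)
    if exon.strand == "+":
        return ann.extract_sequence(exon.chrom, exon.start, exon.start + flank, "+")
    return ann.extract_sequence(exon.chrom, exon.end - flank, exon.end, "-")


def _make_record(
    ann: GenomeAnnotation,
    gene_id: str,
    donor: ExonRecord,
    acceptor: ExonRecord,
    flank: int,
    status: str,
) -> JunctionRecord:
    left = _donor_flank(ann, donor, flank)
    right = _acceptor_flank(ann, acceptor, flank)
    prefix = "KJ" if status == "known" else "NJ"
    jid = f"{prefix}:{gene_id}:{donor.exon_id}|{acceptor.exon_id}"
    return JunctionRecord(
        junction_id=jid,
        gene_id=gene_id,
        donor_exon=donor.exon_id,
        acceptor_exon=acceptor.exon_id,
        donor_end_phase=donor.end_phase,
        acceptor_start_phase=acceptor.start_phase,
        left_flank=len(left),
        right_flank=len(right),
        sequence=left + right,
        status=status,
    )


def build_known_junction_db(
    ann: GenomeAnnotation,
    read_length: int = DEFAULT_READ_LENGTH,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> JunctionReference:
    """One record per adjacent exon pair of any transcript, deduplicated.

    Flank length per side is ``read_length - min_overhang`` (28 nt for 36-nt
    reads), the minimal span such that any read satisfying the two-sided
    overhang rule aligns entirely within the junction sequence.
    """
    flank = read_length - min_overhang
    records: list[JunctionRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for tid in sorted(ann.transcripts):
        tx = ann.transcripts[tid]
        for donor, acceptor in zip(tx.exons, tx.exons[1:]):
            key = (tx.gene_id, donor.exon_id, acceptor.exon_id)
            if key in seen:
                continue
            seen.add(key)
            records.append(_make_record(ann, tx.gene_id, donor, acceptor, flank, "known"))
    return JunctionReference(records)


def build_novel_junction_db(
    ann: GenomeAnnotation,
    known_db: JunctionReference,
    read_length: int = DEFAULT_READ_LENGTH,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> JunctionReference:
    """Phase-compatible unannotated ordered exon pairs within each gene.

    Candidates pair coding exons of one gene (donor strictly before the
    acceptor in transcription order) whose donor end phase equals the
    acceptor start phase, excluding every annotated adjacency.  Exons
    without defined phases (UTR-only, or only in frame-inconsistent
    transcripts) never participate.
    """
    flank = read_length - min_overhang
    known_pairs = known_db.pairs()
    records: list[JunctionRecord] = []
    for gene_id in sorted(ann.genes):
        exons = ann.exons_of_gene(gene_id)  # transcription order
        coding = [
            e for e in exons if e.start_phase is not None and e.end_phase is not None
        ]
        for i, donor in enumerate(coding):
            for acceptor in coding[i + 1 :]:
                if (donor.exon_id, acceptor.exon_id) in known_pairs:
                    continue
                if donor.end_phase != acceptor.start_phase:
                    continue
                records.append(
                    _make_record(ann, gene_id, donor, acceptor, flank, "novel-candidate")
                )
    return JunctionReference(records)


def read_supports_junction(
    offset: int, read_length: int, left_flank: int, right_flank: int,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> bool:
    """Two-sided overhang rule for a read aligned at ``offset`` on a junction.

    The junction point sits at ``left_flank``; the read must cover at least
    ``min_overhang`` nt on each side (8 is inclusive).
    """
    left_cover = left_flank - offset
    right_cover = offset + read_length - left_flank
    return left_cover >= min_overhang and right_cover >= min_overhang


def detect_junction_reads(
    hits: HitTable,
    reference_ids: Sequence[str],
    junction_db: JunctionReference,
    read_length: int = DEFAULT_READ_LENGTH,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> tuple[dict[str, int], np.ndarray]:
    """Count overhang-satisfying junction reads.

    Returns (per-junction counts, boolean mask over hit rows marking the
    hits that satisfied the overhang rule).  A read aligned to a junction
    without the required two-sided coverage contributes nothing.
    """
    counts: dict[str, int] = {r.junction_id: 0 for r in junction_db.records}
    valid = np.zeros(len(hits), dtype=bool)
    left = np.array([junction_db[rid].left_flank for rid in reference_ids], dtype=np.int64)
    right = np.array([junction_db[rid].right_flank for rid in reference_ids], dtype=np.int64)
    if len(hits) == 0:
        return counts, valid
    lf = left[hits.ref_idx]
    rf = right[hits.ref_idx]
    left_cover = lf - hits.offset
    right_cover = hits.offset + read_length - lf
    valid = (
        (left_cover >= min_overhang)
        & (right_cover >= min_overhang)
        & (hits.offset + read_length <= lf + rf)
    )
    # one junction count per (read, junction) pair, not per duplicate hit
    if valid.any():
        pairs = np.stack([hits.read_idx[valid], hits.ref_idx[valid]], axis=1)
        uniq = np.unique(pairs, axis=0)
        ref_counts = np.bincount(uniq[:, 1], minlength=len(reference_ids))
        for j, rid in enumerate(reference_ids):
            if ref_counts[j]:
                counts[rid] = int(ref_counts[j])
    return counts, valid


def count_valid_offsets(
    read_length: int, left_flank: int, right_flank: int,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> int:
    """Number of start offsets at which a read satisfies the overhang rule.

    For a 36-nt read on 28+28 flanks with an 8-base rule this is 21
    (= L - 2*min_overhang + 1) when the flanks allow it.
    """
    n = 0
    for offset in range(0, left_flank + right_flank - read_length + 1):
        if read_supports_junction(offset, read_length, left_flank, right_flank, min_overhang):
            n += 1
    return n
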