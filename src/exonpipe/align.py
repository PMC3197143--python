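"""Self-contained short-read aligner with a bounded-mismatch contract.

The aligner reports *all* ungapped alignments of a fixed-length read
(default 36 nt) against a reference set with at most ``max_mismatch``
substitutions (default 2).  Completeness follows from the pigeonhole
principle: the read is partitioned into ``max_mismatch + 1`` disjoint
segments of length ``k = floor(L / (m + 1))`` (12 for L=36, m=2); any
alignment with at most m mismatches must leave at least one segment
mismatch-free, so exact lookup of every segment in a k-mer index finds a
superset of all valid alignments, which a full Hamming comparison then
filters.

Everything is vectorized over numpy uint8 code arrays (A,C,G,T -> 0..3,
anything else -> 4).  An ``N`` never matches any reference base and so
always counts as a mismatch; reads with more than ``max_mismatch`` Ns are
discarded up front since no alignment could satisfy the bound.

Hit ordering is deterministic: (read index, reference index, offset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 36
DEFAULT_MAX_MISMATCH = 2

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# complement codes: A<->T, C<->G, N -> N
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_reads(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length reads into an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    buf = "".join(seqs)
    arr = encode(buf)
    return arr.reshape(len(seqs), -1)


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[..., ::-1]]


@dataclass
class AlignmentHit:
    """One ungapped alignment of a read against a reference."""

    read_id: str
    reference_id: str
    offset: int
    mismatches: int
    strand: str = "+"


@dataclass
class HitTable:
    """Column-oriented alignment results for one batch of reads.

    ``read_idx`` indexes into the batch's read list; ``ref_idx`` into the
    index's reference list.  ``strand`` is ``+1`` for forward, ``-1`` for
    reverse-complement alignments.
    """

    read_idx: np.ndarray
    ref_idx: np.ndarray
    offset: np.ndarray
    mismatches: np.ndarray
    strand: np.ndarray

    @classmethod
    def empty(cls) -> "HitTable":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), np.empty(0, dtype=np.int64), z.copy())

    def __len__(self) -> int:
        return len(self.read_idx)

    @classmethod
    def concatenate(cls, tables: Iterable["HitTable"]) -> "HitTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return cls.empty()
        return cls(
            np.concatenate([t.read_idx for t in tables]),
            np.concatenate([t.ref_idx for t in tables]),
            np.concatenate([t.offset for t in tables]),
            np.concatenate([t.mismatches for t in tables]),
            np.concatenate([t.strand for t in tables]),
        )

    def sort(self) -> "HitTable":
        order = np.lexsort((self.strand, self.offset, self.ref_idx, self.read_idx))
        return HitTable(
            self.read_idx[order],
            self.ref_idx[order],
            self.offset[order],
            self.mismatches[order],
            self.strand[order],
        )


class ReferenceIndex:
    """Exact-match k-mer index over a reference set.

    References are concatenated into one code array; every window of length
    ``seed_length`` lying fully inside a single reference and free of Ns is
    recorded once in a sorted (k-mer value, position) table, so lookups are
    two binary searches.
    """

    def __init__(self, references: Sequence[tuple[str, str]], seed_length: int = 12):
        if not references:
            raise ValueError("empty reference set")
        ids = [rid for rid, _ in references]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        if not 1 <= seed_length <= 15:  # 4**15 fits comfortably in int64
            raise ValueError(f"seed_length {seed_length} out of range")
        self.ids: list[str] = ids
        self.seed_length = seed_length
        lengths = np.array([len(seq) for _, seq in references], dtype=np.int64)
        self.lengths = lengths
        self.starts = np.concatenate([[0], np.cumsum(lengths)])[:-1]
        self.ends = self.starts + lengths
        self.codes = (
            np.concatenate([encode(seq) for _, seq in references])
            if len(references)
            else np.empty(0, np.uint8)
        )
        self._build_table()

    def _build_table(self) -> None:
        k = self.seed_length
        kmers_parts: list[np.ndarray] = []
        pos_parts: list[np.ndarray] = []
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for start, end in zip(self.starts, self.ends):
            m = end - start
            if m < k:
                continue
            c = self.codes[start:end].astype(np.int64)
            windows = np.lib.stride_tricks.sliding_window_view(c, k)
            vals = windows @ powers
            has_n = np.lib.stride_tricks.sliding_window_view(
                self.codes[start:end] == 4, k
            ).any(axis=1)
            valid = ~has_n
            kmers_parts.append(vals[valid])
            pos_parts.append(np.nonzero(valid)[0] + start)
        if kmers_parts:
            kmers = np.concatenate(kmers_parts)
            positions = np.concatenate(pos_parts)
            order = np.argsort(kmers, kind="stable")
            self.sorted_kmers = kmers[order]
            self.sorted_positions = positions[order]
        else:
            self.sorted_kmers = np.empty(0, dtype=np.int64)
            self.sorted_positions = np.empty(0, dtype=np.int64)

    @property
    def n_indexed_positions(self) -> int:
        return len(self.sorted_kmers)

    def lookup(self, kmer: int) -> np.ndarray:
        """Global positions at which the exact k-mer occurs."""
        lo = np.searchsorted(self.sorted_kmers, kmer, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmer, side="right")
        return np.sort(self.sorted_positions[lo:hi])

    def reference_of(self, global_pos: np.ndarray) -> np.ndarray:
        """Map global concatenated positions to reference indices."""
        return np.searchsorted(self.ends, global_pos, side="right")


def build_index(
    references: Sequence[tuple[str, str]] | dict[str, str], seed_length: int = 12
) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from (id, sequence) pairs or a mapping."""
    if isinstance(references, dict):
        references = list(references.items())
    return ReferenceIndex(references, seed_length)


def _align_codes_batch(
    reads: np.ndarray, index: ReferenceIndex, max_mismatch: int, strand_flag: int
) -> HitTable:
    """All ≤max_mismatch alignments of an (n, L) code matrix; single strand."""
    n, L = reads.shape
    if n == 0:
        return HitTable.empty()
    k = index.seed_length
    n_segments = max_mismatch + 1
    if k * n_segments > L:
        raise ValueError(
            f"seed_length {k} too large for read length {L} with {max_mismatch} mismatches"
        )
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)

    cand_rid: list[np.ndarray] = []
    cand_start: list[np.ndarray] = []
    for s in range(n_segments):
        seg = reads[:, s * k : (s + 1) * k].astype(np.int64)
        seg_kmers = seg @ powers
        seg_valid = ~(reads[:, s * k : (s + 1) * k] == 4).any(axis=1)
        lo = np.searchsorted(index.sorted_kmers, seg_kmers, side="left")
        hi = np.searchsorted(index.sorted_kmers, seg_kmers, side="right")
        cnt = np.where(seg_valid, hi - lo, 0)
        total = int(cnt.sum())
        if total == 0:
            continue
        rid = np.repeat(np.arange(n, dtype=np.int64), cnt)
        base = np.repeat(np.cumsum(cnt) - cnt, cnt)
        posting = np.repeat(lo, cnt) + (np.arange(total, dtype=np.int64) - base)
        pos = index.sorted_positions[posting]
        cand_rid.append(rid)
        cand_start.append(pos - s * k)

    if not cand_rid:
        return HitTable.empty()
    rid = np.concatenate(cand_rid)
    start = np.concatenate(cand_start)

    # deduplicate (read, start) candidate diagonals
    total_len = int(index.ends[-1])
    combo = rid * (total_len + L) + (start + L)  # shift keeps starts nonnegative
    combo, uniq_idx = np.unique(combo, return_index=True)
    rid = rid[uniq_idx]
    start = start[uniq_idx]

    # keep windows fully inside a single reference
    ref_idx = index.reference_of(start)
    ok = (start >= 0) & (start >= index.starts[ref_idx]) & (start + L <= index.ends[ref_idx])
    rid, start, ref_idx = rid[ok], start[ok], ref_idx[ok]
    if len(rid) == 0:
        return HitTable.empty()

    windows = index.codes[start[:, None] + np.arange(L)]
    mism = (windows != reads[rid]).sum(axis=1)
    ok = mism <= max_mismatch
    rid, start, ref_idx, mism = rid[ok], start[ok], ref_idx[ok], mism[ok]
    offset = start - index.starts[ref_idx]
    strand = np.full(len(rid), strand_flag, dtype=np.int64)
    return HitTable(rid, ref_idx, offset, mism.astype(np.int64), strand)


def align_batch(
    reads: np.ndarray,
    index: ReferenceIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    both_strands: bool = False,
    chunk_size: int = 32768,
) -> HitTable:
    """Align an (n, L) uint8 code matrix; returns a sorted :class:`HitTable`.

    With ``both_strands`` the reverse complement of each read is also
    aligned and reported with strand -1 (used for the genome stage of the
    exon-level pipeline; transcript and junction references are sense-strand).
    """
    n = reads.shape[0]
    parts: list[HitTable] = []
    for beg in range(0, n, chunk_size):
        chunk = reads[beg : beg + chunk_size]
        sub = _align_codes_batch(chunk, index, max_mismatch, 1)
        sub.read_idx += beg
        parts.append(sub)
        if both_strands:
            rc = reverse_complement_codes(chunk)
            sub_rc = _align_codes_batch(rc, index, max_mismatch, -1)
            sub_rc.read_idx += beg
            parts.append(sub_rc)
    return HitTable.concatenate(parts).sort()


def align_read(
    read: str,
    index: ReferenceIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    read_id: str = "read",
) -> list[AlignmentHit]:
    """Align a single read; convenience wrapper over :func:`align_batch`."""
    codes = encode_reads([read])
    table = align_batch(codes, index, max_mismatch)
    return [
        AlignmentHit(read_id, index.ids[r], int(o), int(m), "+" if s > 0 else "-")
        for r, o, m, s in zip(table.ref_idx, table.offset, table.mismatches, table.strand)
    ]


@dataclass
class ReadBatch:
    """Reads of one sample: ids plus an (n, L) uint8 code matrix."""

    ids: list[str]
    codes: np.ndarray
    n_discarded: int = 0  # too short or too many Ns

    def __len__(self) -> int:
        return len(self.ids)


def load_fastq(handle, read_length: int = DEFAULT_READ_LENGTH,
               max_mismatch: int = DEFAULT_MAX_MISMATCH) -> ReadBatch:
    """Read single-end FASTQ into a :class:`ReadBatch`.

    Reads shorter than ``read_length`` or containing more than
    ``max_mismatch`` Ns are dropped and counted.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    ids: list[str] = []
    seqs: list[str] = []
    n_discarded = 0
    for title, seq, _qual in FastqGeneralIterator(handle):
        if len(seq) < read_length or seq.upper().count("N") > max_mismatch:
            n_discarded += 1
            continue
        ids.append(title.split()[0])
        seqs.append(seq[:read_length].upper())
    if n_discarded:
        logger.warning("discarded %d reads (short or >%d Ns)", n_discarded, max_mismatch)
    return ReadBatch(ids, encode_reads(seqs), n_discarded)


@dataclass
class StageResult:
    """Alignment outcome of one hierarchical stage."""

    name: str
    hits: HitTable  # read_idx refers to the *original* batch order
    reference_ids: list[str]
    n_aligned: int


@dataclass
class HierarchicalResult:
    stages: list[StageResult] = field(default_factory=list)
    unaligned: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_reads: int = 0

    def tally(self) -> dict[str, int]:
        out = {s.name: s.n_aligned for s in self.stages}
        out["unaligned"] = len(self.unaligned)
        out["total"] = self.n_reads
        return out


def align_hierarchical(
    batch: ReadBatch,
    stages: Sequence[tuple[str, ReferenceIndex, bool]],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> HierarchicalResult:
    """Waterfall alignment: each read is consumed by the first stage hitting it.

    ``stages`` is an ordered list of (name, index, both_strands).  The two
    pipelines used downstream are gene-level ``[transcriptome]`` and
    exon-level ``[genome, known-junction, novel-junction]``: reads that fail
    to map to the genome are tried against known junctions, and only reads
    unmapped there are offered to the novel-junction references.
    """
    remaining = np.arange(len(batch), dtype=np.int64)
    result = HierarchicalResult(n_reads=len(batch))
    for name, index, both in stages:
        if len(remaining) == 0:
            result.stages.append(
                StageResult(name, HitTable.empty(), list(index.ids), 0)
            )
            continue
        table = align_batch(batch.codes[remaining], index, max_mismatch, both_strands=both)
        table.read_idx = remaining[table.read_idx]
        aligned_mask = np.zeros(len(batch), dtype=bool)
        aligned_mask[table.read_idx] = True
        n_aligned = int(aligned_mask[remaining].sum())
        result.stages.append(StageResult(name, table, list(index.ids), n_aligned))
        remaining = remaining[~aligned_mask[remaining]]
    result.unaligned = remaining
    return result


def brute_force_hits(
    read: str, references: Sequence[tuple[str, str]], max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> list[tuple[str, int, int]]:
    """Exhaustive Hamming scan oracle: all (ref id, offset, mismatches).

    Independent of the seeded path; quadratic and only meant for validating
    the pigeonhole aligner on small fixtures.
    """
    out: list[tuple[str, int, int]] = []
    r = encode(read.upper())
    L = len(r)
    for rid, seq in references:
        c = encode(seq.upper())
        if len(c) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(c, L)
        mm = (windows != r).sum(axis=1)
        for off in np.nonzero(mm <= max_mismatch)[0]:
            out.append((rid, int(off), int(mm[off])))
    return sorted(out)
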