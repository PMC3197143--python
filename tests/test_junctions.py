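"""Junction databases: flanks, dedup, phase filter, overhang rule."""

from itertools import combinations

import pytest

from exonpipe import junctions as jx
from exonpipe.annotation import annotation_from_string
from exonpipe.simulate import SimulationConfig, generate_genome_annotation
from tests.conftest import gtf_line, random_sequence


@pytest.fixture(scope="module")
def toy_dbs(request):
    toy_gtf = request.getfixturevalue("toy_gtf")
    toy_genome = request.getfixturevalue("toy_genome")
    ann = annotation_from_string(toy_gtf, toy_genome)
    known = jx.build_known_junction_db(ann)
    novel = jx.build_novel_junction_db(ann, known)
    return ann, known, novel


class TestKnownDb:
    def test_two_exon_transcript_gives_one_junction(self):
        gtf = "".join(
            gtf_line("chr1", f, s, e, "+", "g", "t", name)
            for name, s, e in (("x1", 0, 40), ("x2", 100, 150))
            for f in ("exon",)
        )
        ann = annotation_from_string(gtf, f">chr1\n{random_sequence(200, 1)}\n")
        assert len(jx.build_known_junction_db(ann)) == 1

    def test_shared_chain_deduplicated(self):
        # 3 transcripts all using the chain x1-x2-x3 -> 2 junctions
        rows = []
        for tx in ("t1", "t2", "t3"):
            for name, s, e in (("x1", 0, 40), ("x2", 100, 150), ("x3", 200, 260)):
                rows.append(gtf_line("chr1", "exon", s, e, "+", "g", tx, name))
        ann = annotation_from_string("".join(rows), f">chr1\n{random_sequence(300, 2)}\n")
        known = jx.build_known_junction_db(ann)
        assert len(known) == 2
        assert known.pairs() == {("x1", "x2"), ("x2", "x3")}

    def test_flank_arithmetic(self, toy_dbs):
        _, known, _ = toy_dbs
        rec = known[f"KJ:GB:E5|E6"]
        assert (rec.left_flank, rec.right_flank) == (28, 28)
        assert len(rec.sequence) == 56

    def test_flank_truncated_to_short_exon(self):
        gtf = "".join(
            gtf_line("chr1", "exon", s, e, "+", "g", "t", name)
            for name, s, e in (("x1", 0, 15), ("x2", 100, 160))
        )
        ann = annotation_from_string(gtf, f">chr1\n{random_sequence(200, 3)}\n")
        rec = jx.build_known_junction_db(ann).records[0]
        assert (rec.left_flank, rec.right_flank) == (15, 28)

    def test_junction_sequence_matches_cdna(self, toy_dbs):
        ann, known, _ = toy_dbs
        cdna = ann.transcript_cdna("TB1")
        rec = known["KJ:GB:E4|E5"]
        boundary = 36  # E4 length
        expected = cdna[boundary - rec.left_flank : boundary + rec.right_flank]
        assert rec.sequence == expected


class TestNovelDb:
    def test_all_phase0_gene_enumerates_skips(self, toy_dbs):
        # GB: 4 coding exons, all lengths % 3 == 0 -> phases all 0;
        # known {4-5, 5-6, 6-7} -> novel {4-6, 4-7, 5-7}
        _, _, novel = toy_dbs
        gb = {(r.donor_exon, r.acceptor_exon) for r in novel.records if r.gene_id == "GB"}
        assert gb == {("E4", "E6"), ("E4", "E7"), ("E5", "E7")}

    def test_phase_filter_excludes_frameshifting_pairs(self):
        # lengths 10/21/35/24: end phases 1,1,0,0 / start phases 0,1,1,0.
        # Unannotated ordered pairs: (1,3) in phase (1==1) -> emitted;
        # (1,4) 1 vs 0 and (2,4) 1 vs 0 -> excluded.
        rows = []
        for name, s, e in (("x1", 0, 10), ("x2", 60, 81), ("x3", 140, 175),
                           ("x4", 230, 254)):
            rows.append(gtf_line("chr1", "exon", s, e, "+", "g", "t", name))
            rows.append(gtf_line("chr1", "CDS", s, e, "+", "g", "t", name))
        ann = annotation_from_string("".join(rows), f">chr1\n{random_sequence(300, 4)}\n")
        known = jx.build_known_junction_db(ann)
        novel = jx.build_novel_junction_db(ann, known)
        assert {(r.donor_exon, r.acceptor_exon) for r in novel.records} == {("x1", "x3")}

    def test_two_exon_gene_has_no_candidates(self):
        gtf = "".join(
            line
            for name, s, e in (("x1", 0, 30), ("x2", 100, 160))
            for line in (
                gtf_line("chr1", "exon", s, e, "+", "g", "t", name),
                gtf_line("chr1", "CDS", s, e, "+", "g", "t", name),
            )
        )
        ann = annotation_from_string(gtf, f">chr1\n{random_sequence(200, 5)}\n")
        known = jx.build_known_junction_db(ann)
        assert len(jx.build_novel_junction_db(ann, known)) == 0

    def test_utr_only_exons_never_pair(self, toy_dbs):
        # gene GA exons have phases only via TA1; TA2 is frame-inconsistent.
        # All GA pairs are annotated (1-2, 2-3 from TA1; 1-3 from TA2).
        _, _, novel = toy_dbs
        assert not [r for r in novel.records if r.gene_id == "GA"]

    def test_disjoint_from_known(self, toy_dbs):
        _, known, novel = toy_dbs
        assert not (known.pairs() & novel.pairs())

    def test_brute_force_enumeration_agreement(self):
        """Builder output equals brute-force pair enumeration on a synthetic genome."""
        cfg = SimulationConfig(seed=5, n_genes=10, n_pairs=2, reads_per_sample=0,
                               n_novel_skip=1, n_pattern2=1, n_pattern3=1)
        _, _, ann = generate_genome_annotation(cfg)
        known = jx.build_known_junction_db(ann)
        novel = jx.build_novel_junction_db(ann, known)
        expected = set()
        for gene_id in ann.genes:
            exons = ann.exons_of_gene(gene_id)
            for i, j in combinations(range(len(exons)), 2):
                d, a = exons[i], exons[j]
                if d.end_phase is None or a.start_phase is None:
                    continue
                if d.end_phase != a.start_phase:
                    continue
                if (d.exon_id, a.exon_id) in known.pairs():
                    continue
                expected.add((d.exon_id, a.exon_id))
        assert novel.pairs() == expected
        assert len(novel) > 0


class TestOverhangRule:
    def test_boundary_offset_counted(self):
        # 36-nt read at offset 0 of a 28+8 junction: 28 left, 8 right
        assert jx.read_supports_junction(0, 36, 28, 8)

    def test_seven_base_overhang_rejected(self):
        # offset 21 on 28+28 flanks: left cover 7
        assert not jx.read_supports_junction(21, 36, 28, 28)
        # right cover 7: read ends 7 nt past the junction point
        assert not jx.read_supports_junction(0, 36, 29, 7)

    def test_valid_offset_count_is_21(self):
        assert jx.count_valid_offsets(36, 28, 28, 8) == 21

    def test_detect_junction_reads_counts_and_overhang(self, toy_dbs):
        from exonpipe import align as al

        ann, known, _ = toy_dbs
        rec = known["KJ:GB:E4|E5"]
        idx = al.build_index(known.as_references())
        reads = [
            rec.sequence[0:36],    # 28 left / 8 right -> counted
            rec.sequence[20:56],   # 8 left / 28 right -> counted
            rec.sequence[-36:],    # right flank only spillover: offset 20 -> counted
        ]
        batch = al.encode_reads(reads)
        hits = al.align_batch(batch, idx)
        ref_ids = known.as_references()
        counts, valid = jx.detect_junction_reads(hits, [r[0] for r in ref_ids], known)
        assert counts["KJ:GB:E4|E5"] == 3
        assert valid.sum() >= 3
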