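"""Synthetic cohort generator: determinism, frame constraints, planted truth."""

import numpy as np
import pytest

from exonpipe.simulate import (
    SimulationConfig,
    generate_expression_profiles,
    generate_genome_annotation,
    simulate_reads,
)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="deg_fraction"):
            SimulationConfig(deg_fraction=1.5)

    def test_exon_flank_requirement(self):
        with pytest.raises(ValueError, match="flank requirement"):
            SimulationConfig(exon_length=(20, 100))

    def test_sample_sheet_shape(self):
        sheet = SimulationConfig(n_pairs=3).sample_sheet()
        assert len(sheet) == 6
        assert set(sheet["condition"]) == {"tumor", "non-tumor"}


class TestGenomeAnnotation:
    def test_empty_config(self):
        fasta, gtf, ann = generate_genome_annotation(
            SimulationConfig(n_genes=0, n_novel_skip=0, n_pattern2=0, n_pattern3=0)
        )
        assert fasta == "" and gtf == ""
        assert ann.summary() == {"genes": 0, "transcripts": 0, "exons": 0}

    def test_deterministic(self, small_config):
        a = generate_genome_annotation(small_config)
        b = generate_genome_annotation(small_config)
        assert a[0] == b[0] and a[1] == b[1]

    def test_every_transcript_frame_consistent(self, small_config):
        _, _, ann = generate_genome_annotation(small_config)
        assert all(tx.frame_consistent for tx in ann.transcripts.values())
        assert all(tx.cds_length % 3 == 0 for tx in ann.transcripts.values())

    def test_planted_skip_is_phase_compatible(self, small_config):
        """Phases recomputed from the emitted annotation match at the skip."""
        _, _, ann = generate_genome_annotation(small_config)
        _, truth = generate_expression_profiles(ann, small_config)
        for row in truth.junctions.itertuples():
            donor = ann.exons[row.donor_exon]
            acceptor = ann.exons[row.acceptor_exon]
            assert donor.end_phase is not None
            assert donor.end_phase == acceptor.start_phase

    def test_exons_meet_flank_requirement(self, small_config):
        _, _, ann = generate_genome_annotation(small_config)
        min_flank = small_config.read_length - small_config.min_overhang
        assert all(e.length >= min_flank for e in ann.exons.values())


class TestExpressionProfiles:
    def test_zero_deg_fraction(self):
        cfg = SimulationConfig(seed=3, n_genes=10, n_pairs=2, deg_fraction=0.0,
                               n_novel_skip=0, n_pattern2=0, n_pattern3=0)
        _, _, ann = generate_genome_annotation(cfg)
        _, truth = generate_expression_profiles(ann, cfg)
        assert not truth.genes["is_DEG"].any()
        assert (truth.genes["true_log2fc"] == 0).all()

    def test_planted_fold_change_recovered_in_expectation(self):
        """Mean tumor/normal abundance ratio of +2 log2FC genes is ~4."""
        ratios = []
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed, n_genes=10, n_pairs=4, deg_fraction=0.4,
                n_novel_skip=0, n_pattern2=0, n_pattern3=0,
            )
            abund, truth = generate_expression_profiles(None, cfg)
            genes = truth.genes.set_index("gene_id")
            up = genes.index[genes["is_DEG"] & (genes["direction"] == "up")]
            tumor = [c for c in abund.columns if c.endswith("T")]
            normal = [c for c in abund.columns if c.endswith("N")]
            for g in up:
                tx = f"{g}.T1"
                ratios.append(
                    abund.loc[tx, tumor].mean() / abund.loc[tx, normal].mean()
                )
        assert np.log2(np.mean(ratios)) == pytest.approx(2.0, abs=0.15)

    def test_pattern3_exon_truth_has_both_directions(self, small_config):
        _, truth = generate_expression_profiles(None, small_config)
        genes = truth.genes.set_index("gene_id")
        p3 = genes.index[genes["pattern"] == "3"]
        assert len(p3) == 1
        exons = truth.exons[truth.exons["gene_id"] == p3[0]]
        dirs = set(exons.loc[exons["is_DEE"], "direction"])
        assert dirs == {"up", "down"}

    def test_pattern2_dees_one_direction_with_flat_exons(self, small_config):
        _, truth = generate_expression_profiles(None, small_config)
        genes = truth.genes.set_index("gene_id")
        p2 = genes.index[genes["pattern"] == "2"][0]
        exons = truth.exons[truth.exons["gene_id"] == p2]
        assert set(exons.loc[exons["is_DEE"], "direction"]) == {"up"}
        assert (~exons["is_DEE"]).any()

    def test_output_balance(self, small_config):
        """Expected read yield is equal across conditions (composition-safe)."""
        _, _, ann = generate_genome_annotation(small_config)
        abund, truth = generate_expression_profiles(ann, small_config)
        L = small_config.read_length
        lengths = {}
        for tid in abund.index:
            if tid in ann.transcripts:
                lengths[tid] = ann.transcripts[tid].cdna_length
            else:
                chain = truth.novel_transcripts[tid]
                lengths[tid] = sum(ann.exons[e].length for e in chain)
        w = np.array([max(lengths[t] - L + 1, 1) for t in abund.index])
        tumor = [c for c in abund.columns if c.endswith("T")]
        normal = [c for c in abund.columns if c.endswith("N")]
        # compare expected (noise-free) yields via many-seed average
        yt = (abund[tumor].to_numpy() * w[:, None]).sum()
        yn = (abund[normal].to_numpy() * w[:, None]).sum()
        assert abs(np.log2(yt / yn)) < 0.25  # patient noise only


class TestReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimulationConfig(seed=9, n_genes=2, n_pairs=1, reads_per_sample=10,
                               error_rate=0.0, n_novel_skip=0, n_pattern2=0,
                               n_pattern3=0, deg_fraction=0.0)
        _, _, ann = generate_genome_annotation(cfg)
        abund, truth = generate_expression_profiles(ann, cfg)
        fq = simulate_reads(ann, abund, cfg, truth.novel_transcripts)
        cdna = {t: ann.transcript_cdna(t) for t in ann.transcripts}
        for text in fq.values():
            lines = text.strip().split("\n")
            for i in range(0, len(lines), 4):
                header, seq = lines[i], lines[i + 1]
                _, tx, start, _ = header[1:].split(":")
                assert cdna[tx][int(start) : int(start) + 36] == seq

    def test_same_seed_identical_fastq(self, small_config):
        _, _, ann = generate_genome_annotation(small_config)
        abund, truth = generate_expression_profiles(ann, small_config)
        a = simulate_reads(ann, abund, small_config, truth.novel_transcripts)
        b = simulate_reads(ann, abund, small_config, truth.novel_transcripts)
        assert a == b

    def test_read_counts_match_config(self, small_config):
        _, _, ann = generate_genome_annotation(small_config)
        abund, truth = generate_expression_profiles(ann, small_config)
        fq = simulate_reads(ann, abund, small_config, truth.novel_transcripts)
        for text in fq.values():
            assert text.count("\n") // 4 == small_config.reads_per_sample

    def test_tumor_samples_contain_junction_spanning_reads(self):
        """At inclusion 1.0 every tumor sample yields >=1 read spanning the
        planted junction with >=8 nt on each side."""
        cfg = SimulationConfig(seed=13, n_genes=8, n_pairs=3, reads_per_sample=20000,
                               n_novel_skip=1, n_pattern2=0, n_pattern3=0,
                               deg_fraction=0.0)
        _, _, ann = generate_genome_annotation(cfg)
        abund, truth = generate_expression_profiles(ann, cfg)
        fq = simulate_reads(ann, abund, cfg, truth.novel_transcripts)
        row = truth.junctions.iloc[0]
        chain = truth.novel_transcripts[row.skip_isoform]
        donor_pos = chain.index(row.donor_exon)
        junction = sum(ann.exons[e].length for e in chain[: donor_pos + 1])
        lo, hi = junction - 28, junction - 8  # start window satisfying overhang
        for sample, text in fq.items():
            if not sample.endswith("T"):
                continue
            spanning = 0
            for line in text.split("\n"):
                if line.startswith("@") and f":{row.skip_isoform}:" in line:
                    start = int(line.split(":")[2])
                    if lo <= start <= hi:
                        spanning += 1
            assert spanning >= 1, sample
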