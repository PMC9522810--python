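"""Candidate pileup, read classification, filter cascade and detection."""

import numpy as np
import pysam
import pytest

from ironspot import regions as rg, scoring as sc, simulate as sim, vcfio
from ironspot.detect import (
    CandidateVariant,
    DetectConfig,
    ReadClassCounts,
    cascade_filter,
    classify_reads,
    detect,
    merge_distinct,
    normalize_variant,
    pileup_candidates,
    population_af_filter,
    position_diversity_filter,
)
from _toolkit import brute_classify, make_bam, random_dna, write_fasta


def _locus(tmp_path, n_alt, n_ref, alt_base="A", seed=0, read_len=50):
    """A two-exon plus-strand locus with contiguous reads over the donor
    window; n_alt of them carry alt_base at the 3rd intronic position."""
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 600)
    pos = 202  # inside donor window [197, 206)
    seq = seq[:pos] + "G" + seq[pos + 1 :]
    fasta = write_fasta(tmp_path / "ref.fa", {"chr1": seq})
    region = rg.SpliceSiteRegion("chr1", 200, "donor", "+", (197, 206), (200, 300), ("T",))
    reads = []
    for i in range(n_alt + n_ref):
        start = 160 + (i % 40)
        rseq = seq[start : start + read_len]
        if i < n_alt:
            off = pos - start
            rseq = rseq[:off] + alt_base + rseq[off + 1 :]
        reads.append((f"r{i}", "chr1", start, f"{read_len}M", rseq))
    bam = make_bam(tmp_path / "reads.bam", {"chr1": 600}, reads)
    return bam, fasta, region, pos


class TestPileup:
    @pytest.mark.parametrize(
        "n_alt, n_ref, expected",
        [
            (3, 37, True),    # vaf 0.075, 3 supports: kept
            (4, 96, False),   # vaf 0.04: below the VAF floor
            (2, 8, False),    # only two supporting reads
        ],
    )
    def test_support_and_vaf_thresholds(self, tmp_path, n_alt, n_ref, expected):
        bam, fasta, region, pos = _locus(tmp_path, n_alt, n_ref)
        with pysam.AlignmentFile(bam) as aln, pysam.FastaFile(fasta) as genome:
            cands = pileup_candidates(aln, [region], genome)
        keys = {c.key for c, _ in cands}
        assert (("chr1", pos, "G", "A") in keys) is expected

    def test_zero_depth_window_yields_nothing(self, tmp_path):
        bam, fasta, region, _ = _locus(tmp_path, 0, 0)
        empty = make_bam(tmp_path / "empty.bam", {"chr1": 600}, [])
        with pysam.AlignmentFile(empty) as aln, pysam.FastaFile(fasta) as genome:
            assert pileup_candidates(aln, [region], genome) == []

    def test_low_mapq_reads_excluded(self, tmp_path):
        bam, fasta, region, pos = _locus(tmp_path, 5, 5)
        with pysam.AlignmentFile(bam) as aln, pysam.FastaFile(fasta) as genome:
            cands = pileup_candidates(
                aln, [region], genome, DetectConfig(min_mapq=80)
            )
        assert cands == []


class TestNormalization:
    def test_snv_unchanged(self, tmp_path):
        fasta = write_fasta(tmp_path / "r.fa", {"c": "ACGTACGTAC"})
        with pysam.FastaFile(fasta) as genome:
            assert normalize_variant(genome, "c", 4, "A", "G") == (4, "A", "G")

    def test_right_trim_and_left_align_in_repeat(self, tmp_path):
        # deletion of one "CA" in a CACACA repeat left-aligns to the start
        fasta = write_fasta(tmp_path / "r.fa", {"c": "GGCACACATT"})
        with pysam.FastaFile(fasta) as genome:
            pos, ref, alt = normalize_variant(genome, "c", 5, "ACA", "A")
            assert (pos, ref, alt) == (1, "GCA", "G")

    def test_padded_snv_trims_to_minimal(self, tmp_path):
        fasta = write_fasta(tmp_path / "r.fa", {"c": "ACGTACGTAC"})
        with pysam.FastaFile(fasta) as genome:
            assert normalize_variant(genome, "c", 4, "ACG", "AGG") == (5, "C", "G")


class TestPositionDiversity:
    def _cand(self, offsets, read_len=50):
        return CandidateVariant(
            "chr1", 202, "G", "A", 50, len(offsets),
            frozenset(offsets),
            frozenset(min(o, read_len - 1 - o) for o in offsets),
        )

    def test_three_positions_with_interior_support_pass(self):
        cand = self._cand({12, 30, 48})
        assert position_diversity_filter(cand, edge_rule="outside")
        assert position_diversity_filter(cand, edge_rule="inside")

    def test_single_position_fails(self):
        assert not position_diversity_filter(self._cand({20}))

    def test_two_positions_fail(self):
        assert not position_diversity_filter(self._cand({10, 25}))

    def test_edge_rules_differ_on_edge_only_support(self):
        cand = self._cand({0, 2, 47})  # all within 5 bases of an edge
        assert position_diversity_filter(cand, edge_rule="inside")
        assert not position_diversity_filter(cand, edge_rule="outside")


class TestClassifyReads:
    def test_retention_read_with_alt_is_ir_pos(self, tmp_path):
        bam, fasta, region, pos = _locus(tmp_path, 4, 0)
        cand = CandidateVariant("chr1", pos, "G", "A", 4, 4, frozenset({1}), frozenset({1}))
        with pysam.AlignmentFile(bam) as aln, pysam.FastaFile(fasta) as genome:
            counts = classify_reads(aln, region, cand, genome)
        assert counts.ir_pos == 4 and counts.ir_neg == 0

    def test_spliced_read_with_ref_is_sj_neg(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 600)
        fasta = write_fasta(tmp_path / "ref.fa", {"chr1": seq})
        region = rg.SpliceSiteRegion("chr1", 200, "donor", "+", (197, 206), (200, 300), ("T",))
        rseq = seq[175:200] + seq[300:325]
        bam = make_bam(tmp_path / "sj.bam", {"chr1": 600},
                       [("s1", "chr1", 175, "25M100N25M", rseq)])
        cand = CandidateVariant("chr1", 202, seq[202], "A" if seq[202] != "A" else "C",
                                1, 1, frozenset({1}), frozenset({1}))
        with pysam.AlignmentFile(bam) as aln, pysam.FastaFile(fasta) as genome:
            counts = classify_reads(aln, region, cand, genome)
        assert counts.sj_neg == 1 and counts.ir_pos == 0

    def test_read_ending_at_variant_ties_to_negative(self, tmp_path):
        """A retention read stopping right before the variant base scores
        both haplotypes equally and must count as variant-negative."""
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 600)
        fasta = write_fasta(tmp_path / "ref.fa", {"chr1": seq})
        region = rg.SpliceSiteRegion("chr1", 200, "donor", "+", (197, 206), (200, 300), ("T",))
        rseq = seq[152:202]  # covers the boundary, stops before pos 202
        bam = make_bam(tmp_path / "tie.bam", {"chr1": 600},
                       [("t1", "chr1", 152, "50M", rseq)])
        cand = CandidateVariant("chr1", 202, seq[202], "A" if seq[202] != "A" else "C",
                                1, 1, frozenset({1}), frozenset({1}))
        with pysam.AlignmentFile(bam) as aln, pysam.FastaFile(fasta) as genome:
            counts = classify_reads(aln, region, cand, genome)
        assert counts.ir_neg == 1 and counts.ir_pos == 0

    def test_partition_matches_brute_force_on_scene(self, planted_scene, scene_genome):
        """Four-way read partition equals an exhaustive independent
        classifier at every planted boundary (both strands present)."""
        with pysam.AlignmentFile(planted_scene.rna_bam) as aln:
            for plant in planted_scene.truth["plants"]:
                region = next(
                    r for r in planted_scene.regions
                    if r.chrom == plant["chrom"]
                    and r.boundary == plant["boundary"]
                    and r.side == plant["side"]
                )
                cand = CandidateVariant(
                    plant["chrom"], plant["pos"], plant["ref"], plant["alt"],
                    10, 5, frozenset({1}), frozenset({1}),
                )
                counts = classify_reads(aln, region, cand, scene_genome)
                expected = brute_classify(
                    planted_scene.rna_bam, region, plant["pos"], plant["alt"]
                )
                got = (counts.sj_pos, counts.sj_neg, counts.ir_pos, counts.ir_neg)
                assert got == expected


class TestCascade:
    @pytest.mark.parametrize(
        "counts, ok",
        [
            (ReadClassCounts(0, 27, 3, 0, 30), True),    # penetrance exactly 0.1
            (ReadClassCounts(0, 0, 3, 1, 30), False),    # specificity 0.75
            (ReadClassCounts(0, 5, 5, 0, 20), False),    # intronic coverage 20 < 25
            (ReadClassCounts(0, 0, 2, 0, 30), False),    # only two retention reads
            (ReadClassCounts(0, 0, 3, 0, 25), True),     # extent boundary inclusive
            (ReadClassCounts(0, 0, 27, 3, 30), True),    # specificity exactly 0.9
        ],
    )
    def test_truth_table(self, counts, ok):
        passed, verdicts = cascade_filter(counts)
        assert passed is ok
        assert len(verdicts) == 4

    def test_raising_any_threshold_never_passes_more(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            counts = ReadClassCounts(
                *(int(x) for x in rng.integers(0, 30, size=4)), int(rng.integers(0, 60))
            )
            base, _ = cascade_filter(counts)
            stricter, _ = cascade_filter(
                counts, min_ir_pos=4, min_specificity=0.95,
                min_penetrance=0.2, min_intronic_cov=30,
            )
            assert base or not stricter


class TestPopulationAf:
    @pytest.mark.parametrize("af, ok", [(0.02, False), (0.01, True), (None, True)])
    def test_strict_threshold(self, af, ok):
        cand = CandidateVariant("chr1", 5, "A", "G", 10, 5, frozenset({1}), frozenset({1}))
        table = {} if af is None else {cand.key: af}
        passed, recorded = population_af_filter(cand, table)
        assert passed is ok
        assert recorded == af

    def test_tsv_and_vcf_loaders_agree(self, tmp_path):
        tsv = tmp_path / "af.tsv"
        tsv.write_text("chrom\tpos\tref\talt\taf\nchr1\t101\tA\tG\t0.004\n")
        vcf = tmp_path / "af.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tA\tG\t.\t.\tAF=0.004\n"
        )
        from ironspot.detect import load_af_table

        t1 = load_af_table(str(tsv))
        t2 = load_af_table(str(vcf))
        assert set(t1) == set(t2) == {("chr1", 100, "A", "G")}
        assert t1[("chr1", 100, "A", "G")] == pytest.approx(t2[("chr1", 100, "A", "G")])


class TestDetectEndToEnd:
    def test_planted_variants_recovered_exactly(self, planted_scene, scene_genome,
                                                scene_models, scene_af):
        regions = rg.exclude_exon_overlapped(planted_scene.regions, planted_scene.models)
        with pysam.AlignmentFile(planted_scene.rna_bam) as aln:
            calls = detect(aln, regions, scene_genome, *scene_models, scene_af,
                           sample_id="s1")
        truth = {(p["chrom"], p["pos"], p["ref"], p["alt"])
                 for p in planted_scene.truth["plants"]}
        found = {c.variant.key for c in calls}
        assert found == truth

    def test_zero_penetrance_yields_no_call(self, tmp_path):
        """An exonic variant carried only by normally spliced reads
        (ir_pos = 0) must not be called."""
        cfg = sim.SimulationConfig(n_genes=2, seed=3, plants=[
            sim.PlantedVariant(0, 0, "donor", 0, ir_penetrance=0.0)
        ])
        scene = sim.simulate_scene(cfg, str(tmp_path / "pen0"))
        with pysam.FastaFile(scene.reference) as genome, \
                pysam.AlignmentFile(scene.rna_bam) as aln:
            donor = sc.train_model(
                [genome.fetch(r.chrom, *sc.scoring_window_span(r)).upper()
                 if r.strand == "+" else
                 sc.reverse_complement(genome.fetch(r.chrom, *sc.scoring_window_span(r)).upper())
                 for r in scene.regions if r.side == "donor"] * 6, "donor")
            acceptor = sc.train_model(
                [genome.fetch(r.chrom, *sc.scoring_window_span(r)).upper()
                 if r.strand == "+" else
                 sc.reverse_complement(genome.fetch(r.chrom, *sc.scoring_window_span(r)).upper())
                 for r in scene.regions if r.side == "acceptor"] * 6, "acceptor")
            calls = detect(aln, scene.regions, genome, donor, acceptor, {})
        assert calls == []

    def test_empty_alignment_gives_empty_list(self, tmp_path, planted_scene,
                                              scene_genome, scene_models):
        empty = make_bam(tmp_path / "none.bam",
                         {m.chrom: 10_000 for m in planted_scene.models}, [])
        with pysam.AlignmentFile(empty) as aln:
            calls = detect(aln, planted_scene.regions, scene_genome,
                           *scene_models, {})
        assert calls == []

    def test_raising_cascade_thresholds_never_adds_calls(
        self, planted_scene, scene_genome, scene_models, scene_af
    ):
        with pysam.AlignmentFile(planted_scene.rna_bam) as aln:
            base = detect(aln, planted_scene.regions, scene_genome, *scene_models,
                          scene_af)
            strict = detect(
                aln, planted_scene.regions, scene_genome, *scene_models, scene_af,
                config=DetectConfig(min_ir_pos=6, min_specificity=0.95,
                                    min_penetrance=0.25, min_intronic_cov=40),
            )
        base_keys = {c.variant.key for c in base}
        assert {c.variant.key for c in strict} <= base_keys


class TestMergeDistinct:
    def _call(self, planted_scene, scene_genome, scene_models, scene_af, sample_id):
        with pysam.AlignmentFile(planted_scene.rna_bam) as aln:
            return detect(aln, planted_scene.regions, scene_genome, *scene_models,
                          scene_af, sample_id=sample_id)

    def test_same_variant_across_samples_counts_once(
        self, planted_scene, scene_genome, scene_models, scene_af
    ):
        calls_a = self._call(planted_scene, scene_genome, scene_models, scene_af, "A")
        calls_b = self._call(planted_scene, scene_genome, scene_models, scene_af, "B")
        distinct = merge_distinct(calls_a + calls_b)
        assert len(distinct) == len(calls_a)
        assert all(d.sample_ids == ("A", "B") for d in distinct)

    def test_different_alt_at_same_position_stays_distinct(self):
        def mk(alt, sample):
            cand = CandidateVariant("chr1", 10, "G", alt, 30, 10,
                                    frozenset({1, 8, 20}), frozenset({1, 8, 20}))
            region = rg.SpliceSiteRegion("chr1", 12, "donor", "+", (9, 18),
                                         (12, 112), ("T",))
            from ironspot.detect import IravCall
            return IravCall(cand, region, ReadClassCounts(0, 10, 10, 0, 30),
                            None, None, sample)

        distinct = merge_distinct([mk("A", "s1"), mk("T", "s2"), mk("A", "s3")])
        assert len(distinct) == 2
        by_alt = {d.alt: d.sample_ids for d in distinct}
        assert by_alt["A"] == ("s1", "s3") and by_alt["T"] == ("s2",)


class TestVcfRoundTrip:
    def test_calls_survive_write_parse_bit_exactly(
        self, tmp_path, planted_scene, scene_genome, scene_models, scene_af
    ):
        regions = rg.exclude_exon_overlapped(planted_scene.regions, planted_scene.models)
        with pysam.AlignmentFile(planted_scene.rna_bam) as aln:
            calls = detect(aln, regions, scene_genome, *scene_models, scene_af,
                           sample_id="s1")
        assert calls
        path = tmp_path / "calls.vcf"
        contigs = dict(zip(scene_genome.references, scene_genome.lengths))
        vcfio.write_calls_vcf(str(path), calls, contigs)
        parsed = vcfio.read_calls_vcf(str(path))
        assert [c for c, _, _ in parsed] == calls
        assert all(failed == () for _, failed, _ in parsed)
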