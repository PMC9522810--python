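"""Shared helpers for the test suite: hand-built alignments, brute-force
oracles independent of the library's code paths, and the hand-computed
ClinVar tier fixture."""

from __future__ import annotations

import pysam
from Bio.Seq import Seq

from ironspot.regions import SpliceSiteRegion, TranscriptModel
from ironspot.tiers import ClinvarRecord


# ---------------------------------------------------------------------------
# alignment fabrication

def make_bam(path, contigs, reads):
    """Write an indexed BAM from (qname, chrom, pos, cigar, seq) tuples."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in contigs.items()],
    }
    order = {n: i for i, n in enumerate(contigs)}
    reads = sorted(reads, key=lambda r: (order[r[1]], r[2]))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for qname, chrom, pos, cigar, seq in reads:
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.reference_id = order[chrom]
            a.reference_start = pos
            a.mapping_quality = 60
            a.flag = 0
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            bam.write(a)
    pysam.index(str(path))
    return str(path)


def write_fasta(path, contigs):
    """Write a FASTA (+faidx) from {name: sequence}."""
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(str(path))
    return str(path)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# brute-force read classifier (independent CIGAR walk + direct base lookup)

def _walk_cigar(pos, cigarstring):
    """Reference segments (kind, start, end) with kind in {'aligned','skip'},
    plus per-reference-base query index mapping for aligned matches."""
    import re

    segs = []
    qmap = {}
    q = 0
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigarstring):
        length = int(length)
        if op in "M=X":
            segs.append(("aligned", pos, pos + length))
            for i in range(length):
                qmap[pos + i] = q + i
            pos += length
            q += length
        elif op == "D":
            segs.append(("aligned", pos, pos + length))
            pos += length
        elif op == "N":
            segs.append(("skip", pos, pos + length))
            pos += length
        elif op in "IS":
            q += length
    return segs, qmap


def brute_classify(bam_path, region, pos, alt, min_mapq=20):
    """Exhaustive four-way classification of reads at a boundary.

    A read splices here when a skip edge coincides with the boundary on the
    intronic side; it retains when one merged aligned run straddles the
    boundary.  Variant support is read off the base aligned at the variant
    position (SNV truth).  Returns (sj_pos, sj_neg, ir_pos, ir_neg).
    """
    sj_pos = sj_neg = ir_pos = ir_neg = 0
    with pysam.AlignmentFile(bam_path) as bam:
        for read in bam.fetch(region.chrom, max(0, region.boundary - 1),
                              region.boundary + 1):
            if read.is_secondary or read.is_supplementary or read.is_duplicate \
                    or read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            segs, qmap = _walk_cigar(read.reference_start, read.cigarstring)
            spliced = False
            for kind, s, e in segs:
                if kind != "skip":
                    continue
                if region.intronic_right and s == region.boundary:
                    spliced = True
                if not region.intronic_right and e == region.boundary:
                    spliced = True
            # merge consecutive aligned runs (D does not split coverage)
            runs = []
            for kind, s, e in segs:
                if kind == "skip":
                    continue
                if runs and runs[-1][1] == s:
                    runs[-1][1] = e
                else:
                    runs.append([s, e])
            spanning = any(s < region.boundary < e for s, e in runs)
            if not spliced and not spanning:
                continue
            base = None
            if pos in qmap:
                base = read.query_sequence[qmap[pos]]
            positive = base == alt
            if spliced:
                sj_pos, sj_neg = (sj_pos + 1, sj_neg) if positive else (sj_pos, sj_neg + 1)
            else:
                ir_pos, ir_neg = (ir_pos + 1, ir_neg) if positive else (ir_pos, ir_neg + 1)
    return sj_pos, sj_neg, ir_pos, ir_neg


# ---------------------------------------------------------------------------
# brute-force consequence oracle (independent mRNA assembly + Biopython)

def brute_consequence(model: TranscriptModel, retained_intron, chrom_seq: str):
    """PTC/NMD truth by direct string assembly and Bio.Seq translation."""
    exons = list(model.exons)
    if retained_intron[1] > retained_intron[0]:
        i = list(model.introns).index(tuple(retained_intron))
        exons = exons[:i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2 :]
    mrna = "".join(chrom_seq[s:e] for s, e in exons)
    exon_list = exons
    if model.strand == "-":
        mrna = str(Seq(mrna).reverse_complement())
        exon_list = exons[::-1]

    def g2t(gpos):
        off = 0
        for s, e in exon_list:
            if s <= gpos < e:
                return off + (gpos - s if model.strand == "+" else e - 1 - gpos)
            off += e - s
        raise AssertionError("position not exonic")

    if model.strand == "+":
        cds_s = g2t(model.cds_start)
        cds_e = g2t(model.cds_end - 1) + 1
    else:
        cds_s = g2t(model.cds_end - 1)
        cds_e = g2t(model.cds_start) + 1
    coding = mrna[cds_s:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    stop_idx = protein.find("*")
    first_stop = cds_s + 3 * stop_idx if stop_idx >= 0 else None
    original_stop = cds_e - 3
    ptc = first_stop if (first_stop is not None and first_stop < original_stop) else None
    lengths = [e - s for s, e in exon_list]
    last_junction = sum(lengths[:-1]) if len(lengths) > 1 else None
    if ptc is None:
        nmd = "not_applicable"
    elif last_junction is not None and ptc < last_junction - 50:
        nmd = "sensitive"
    else:
        nmd = "insensitive"
    return {"ptc_created": ptc is not None, "ptc_mrna_pos": ptc,
            "last_junction_mrna_pos": last_junction, "nmd_class": nmd}


# ---------------------------------------------------------------------------
# the hand-computed ClinVar tier fixture (20 cases)

TIER_GENE = TranscriptModel(
    transcript_id="TTX1",
    gene_symbol="TGENE",
    chrom="chrT",
    strand="+",
    exons=((100, 200), (300, 400), (500, 600)),
    cds_start=110,
    cds_end=590,
)
# the call under classification: donor site of intron 1, variant at +2
TIER_REGION = SpliceSiteRegion(
    chrom="chrT", boundary=200, side="donor", strand="+",
    window=(197, 206), intron=(200, 300), transcript_ids=("TTX1",),
)
TIER_CALL = {"chrom": "chrT", "pos0": 201, "ref": "T", "alt": "A"}

_SOLID = "criteria_provided,_multiple_submitters,_no_conflicts"
_WEAK = "criteria_provided,_single_submitter"
_SPLICE_D = ("splice_donor_variant",)
_SPLICE_A = ("splice_acceptor_variant",)
_NONSENSE = ("nonsense",)
_FRAMESHIFT = ("frameshift_variant",)


def _rec(pos, ref="T", alt="A", clnsig="Pathogenic", mc=(), review=_SOLID,
         gene="TGENE", chrom="chrT"):
    return ClinvarRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, clnsig=clnsig,
                         mc=mc, review_status=review, gene=gene)


# Each case: (name, clinvar record list, nmd_sensitive, expected pathogenic
# tier, expected drug tier).  Transcript coordinates for reference: the
# boundary's last exonic base (genomic 199) sits at mRNA position 99; exonic
# genomic 170 -> mRNA 70 (distance 29), genomic 169 -> 69 (30), genomic
# 168 -> 68 (31); exon-2 genomic 300 -> mRNA 100 (distance 1).
TIER_CASES = [
    ("exact_match", [_rec(202)], True, 1, 5),
    ("exact_needs_same_alt", [_rec(202, alt="G", mc=_SPLICE_D)], True, 2, 5),
    ("exact_likely_pathogenic", [_rec(202, clnsig="Likely_pathogenic")], True, 1, 5),
    ("exact_combined_plp", [_rec(202, clnsig="Pathogenic/Likely_pathogenic")], True, 1, 5),
    ("benign_ignored", [_rec(202, clnsig="Benign")], True, 5, 5),
    ("tier2_same_window_donor", [_rec(199, mc=_SPLICE_D)], True, 2, 5),
    ("tier2_acceptor_tag_accepted", [_rec(205, mc=_SPLICE_A)], True, 2, 5),
    ("tier2_needs_splice_mc", [_rec(199, mc=_NONSENSE)], True, 3, 5),
    ("tier2_outside_window", [_rec(207, mc=_SPLICE_D)], True, 5, 5),
    ("tier3_within_30bp", [_rec(171, mc=_NONSENSE)], True, 3, 5),
    ("tier3_at_30bp_inclusive", [_rec(170, mc=_NONSENSE)], True, 3, 5),
    ("tier3_at_31bp_excluded_nmd_off", [_rec(169, mc=_NONSENSE)], False, 5, 5),
    ("tier3_frameshift_tag", [_rec(301, mc=_FRAMESHIFT)], False, 3, 5),
    ("tier3_intronic_cannot_match", [_rec(251, mc=_NONSENSE, review=_WEAK)], False, 5, 5),
    ("tier4_same_gene_solid", [_rec(551, mc=_NONSENSE)], True, 4, 5),
    ("tier4_needs_solid_review", [_rec(551, mc=_NONSENSE, review=_WEAK)], True, 5, 5),
    ("tier4_needs_nmd_sensitive", [_rec(551, mc=_NONSENSE)], False, 5, 5),
    ("tier4_needs_truncating", [_rec(551, mc=("missense_variant",))], True, 5, 5),
    ("drug_exact", [_rec(202, clnsig="Drug_response")], True, 5, 1),
    ("drug_tier4_same_gene", [_rec(551, clnsig="Drug_response", mc=_NONSENSE)], True, 5, 4),
]
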