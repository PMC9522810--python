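"""Synthetic scenes for the whole pipeline.

The simulator fabricates a small reference genome of multi-exon genes on
both strands with canonical splice motifs, an annotation table, spliced
RNA-seq alignments in which planted boundary variants drive intron
retention at a configurable allele fraction and penetrance, matched
tumor/normal DNA alignments, a toy population allele-frequency table and a
toy ClinVar-style VCF — together with a truth file, so detection,
quantification, consequence, status and tier calling are all testable with
no external data.

Reads are emitted as already-aligned BAM records with exact CIGARs (M/N),
so the truth is exact; a FASTQ export is available for users who want to
push the reads through a real aligner.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .regions import (
    ACCEPTOR,
    DONOR,
    SpliceSiteRegion,
    TranscriptModel,
    build_splice_site_regions,
)
from .scoring import reverse_complement

_ALT_OF = {"A": "C", "C": "A", "G": "T", "T": "G"}

# splice motifs in transcript sense; lowercase marks the essential
# dinucleotides that are never jittered
DONOR_CONSENSUS = "CAGGTAAGT"  # 3 exonic + 6 intronic
DONOR_ESSENTIAL = (3, 4)  # the GT
ACCEPTOR_CONSENSUS = "TTTTTTTTTTTTTTTTTCAGGCA"  # 20 intronic + 3 exonic
ACCEPTOR_ESSENTIAL = (18, 19)  # the AG
MOTIF_CONSENSUS_PROB = 0.9

# genome-forward offsets of the essential dinucleotide within each scan window
ESSENTIAL_WINDOW_OFFSETS = {
    (DONOR, "+"): (3, 4),
    (DONOR, "-"): (4, 5),
    (ACCEPTOR, "+"): (4, 5),
    (ACCEPTOR, "-"): (1, 2),
}


@dataclass(frozen=True)
class PlantedVariant:
    """One planted IRAV: a substitution in a scan window whose carrier
    haplotype retains the adjacent intron with the given penetrance.

    ``alt`` None plants innate retention without any variant (useful for
    fabricating control panels).  ``status`` is the DNA-level truth:
    germline (both DNA samples), somatic (tumor only) or absent (RNA only).
    """

    gene_index: int
    intron_index: int
    side: str
    window_offset: int
    alt: str | None = "auto"
    dna_vaf: float = 0.5
    rna_vaf: float | None = None  # RNA allele fraction; defaults to dna_vaf
    ir_penetrance: float = 1.0
    status: str = "germline"

    @property
    def rna_allele_fraction(self) -> float:
        return self.dna_vaf if self.rna_vaf is None else self.rna_vaf


@dataclass
class SimulationConfig:
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (80, 160)
    intron_len: tuple[int, int] = (80, 200)
    flank: int = 300
    read_length: int = 100
    depth: float = 50.0
    dna_depth: float = 60.0
    error_rate: float = 0.001
    seed: int = 0
    read_seed: int | None = None  # separate read stream; genome stays tied to seed
    sample_id: str = "sample1"
    plants: list[PlantedVariant] = field(default_factory=list)


@dataclass
class Scene:
    """Paths and in-memory objects of one simulated scene."""

    outdir: str
    reference: str
    annotation: str
    rna_bam: str
    tumor_bam: str
    normal_bam: str
    af_table: str
    clinvar_vcf: str
    truth_json: str
    models: list[TranscriptModel]
    regions: list[SpliceSiteRegion]
    truth: dict


# ---------------------------------------------------------------------------
# genome and annotation

def _random_seq(rng, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _sample_motif(rng, consensus: str, essential: tuple[int, ...]) -> str:
    out = []
    for i, c in enumerate(consensus):
        if i in essential or rng.random() < MOTIF_CONSENSUS_PROB:
            out.append(c)
        else:
            out.append("ACGT"[rng.integers(0, 4)])
    return "".join(out)


def _build_gene(rng, cfg: SimulationConfig, index: int):
    """Random gene model plus its chromosome sequence."""
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, size=n_exons)
    intron_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1, size=n_exons - 1)
    strand = "+" if index % 2 == 0 else "-"
    pos = cfg.flank
    exons = []
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    chrom_len = pos + cfg.flank
    seq = _random_seq(rng, chrom_len)

    def put(at: int, motif: str):
        seq[at : at + len(motif)] = [_BASES.tobytes().decode().index(c) for c in motif]

    for i in range(n_exons - 1):
        istart, iend = exons[i][1], exons[i + 1][0]
        donor = _sample_motif(rng, DONOR_CONSENSUS, DONOR_ESSENTIAL)
        acceptor = _sample_motif(rng, ACCEPTOR_CONSENSUS, ACCEPTOR_ESSENTIAL)
        if strand == "+":
            put(istart - 3, donor)
            put(iend - 20, acceptor)
        else:
            put(iend - 6, reverse_complement(donor))
            put(istart - 3, reverse_complement(acceptor))
    # CDS: margin inside first/last exon, trimmed to a codon multiple
    cds_start = exons[0][0] + 9
    cds_end = exons[-1][1] - 9
    exonic = sum(min(e, cds_end) - max(s, cds_start)
                 for s, e in exons if min(e, cds_end) > max(s, cds_start))
    cds_end -= exonic % 3
    model = TranscriptModel(
        transcript_id=f"TX{index + 1:03d}",
        gene_symbol=f"GENE{index + 1}",
        chrom=f"chr{index + 1}",
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    return model, seq


def write_refgene(models: Sequence[TranscriptModel], path: str):
    with open(path, "w") as fh:
        for i, m in enumerate(models):
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                "\t".join(
                    [
                        str(i), m.transcript_id, m.chrom, m.strand,
                        str(m.tx_start), str(m.tx_end),
                        str(m.cds_start), str(m.cds_end),
                        str(len(m.exons)), starts, ends,
                        "0", m.gene_symbol, "cmpl", "cmpl",
                        ",".join("0" for _ in m.exons) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# plant resolution

@dataclass(frozen=True)
class _ResolvedPlant:
    plant: PlantedVariant
    region: SpliceSiteRegion
    pos: int
    ref: str
    alt: str | None
    intron: tuple[int, int]


def _resolve_plants(cfg, models, chrom_seqs) -> list[_ResolvedPlant]:
    resolved = []
    for plant in cfg.plants:
        if not (
            0.0 <= plant.dna_vaf <= 1.0
            and 0.0 <= plant.rna_allele_fraction <= 1.0
            and 0.0 <= plant.ir_penetrance <= 1.0
        ):
            raise ValueError("allele fractions and ir_penetrance must lie in [0, 1]")
        model = models[plant.gene_index]
        regions = [
            r
            for r in build_splice_site_regions([model])
            if r.side == plant.side
            and r.intron == model.introns[plant.intron_index]
        ]
        if not regions:
            raise ValueError(
                f"gene {plant.gene_index} intron {plant.intron_index} has no "
                f"{plant.side} region"
            )
        region = regions[0]
        wlen = region.window[1] - region.window[0]
        if not 0 <= plant.window_offset < wlen:
            raise ValueError(f"window offset {plant.window_offset} outside window")
        pos = region.window[0] + plant.window_offset
        ref = _to_str(chrom_seqs[model.chrom][pos : pos + 1])
        alt = plant.alt
        if alt == "auto":
            alt = _ALT_OF[ref]
        if alt is not None and alt == ref:
            raise ValueError(f"planted alt equals reference base {ref} at {pos}")
        resolved.append(
            _ResolvedPlant(plant, region, pos, ref, alt, model.introns[plant.intron_index])
        )
    return resolved


# ---------------------------------------------------------------------------
# read generation

@dataclass(frozen=True)
class _ReadTruth:
    chrom: str
    start: int
    blocks: tuple[tuple[int, int], ...]
    seq: str
    reverse: bool


def _template_from_blocks(seq_codes, blocks, edits):
    """Concatenate genomic blocks applying single-base edits {pos: base}."""
    parts = []
    for s, e in blocks:
        part = _to_str(seq_codes[s:e])
        for pos, base in edits.items():
            if s <= pos < e:
                idx = pos - s
                part = part[:idx] + base + part[idx + 1 :]
        parts.append(part)
    return "".join(parts)


def _blocks_for_slice(blocks, start, length):
    """Genomic blocks of a template slice [start, start+length)."""
    out = []
    offset = 0
    remaining = length
    for s, e in blocks:
        blen = e - s
        if start >= offset + blen:
            offset += blen
            continue
        local = max(start - offset, 0)
        take = min(blen - local, remaining)
        out.append((s + local, s + local + take))
        remaining -= take
        offset += blen
        if remaining == 0:
            break
    return tuple(out)


def _apply_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < error_rate
    if mask.any():
        idx = np.nonzero(mask)[0]
        for i in idx:
            choices = [b for b in b"ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _blocks_with_retained(model: TranscriptModel, retained: set[tuple[int, int]]):
    """Exon blocks with the given introns absorbed (merged exons)."""
    blocks: list[tuple[int, int]] = [model.exons[0]]
    for i, intron in enumerate(model.introns):
        nxt = model.exons[i + 1]
        if intron in retained:
            blocks[-1] = (blocks[-1][0], nxt[1])
        else:
            blocks.append(nxt)
    return tuple(blocks)


def _gene_rna_reads(rng, cfg, model, seq_codes, plants: list[_ResolvedPlant]):
    """Aligned RNA reads for one gene; returns read truths.

    Each plant is carried independently per read at its DNA allele
    fraction; a carrier read retains the plant's intron with probability
    ``ir_penetrance``.  Variant-free plants (alt None) model innate
    retention on every haplotype.
    """
    rl = cfg.read_length
    normal_blocks = tuple(model.exons)
    reads = []
    tx_len = sum(e - s for s, e in normal_blocks)
    n_reads = max(1, int(round(cfg.depth * tx_len / rl)))
    for _ in range(n_reads):
        edits: dict[int, str] = {}
        retained: set[tuple[int, int]] = set()
        for p in plants:
            carrier = p.alt is not None and rng.random() < p.plant.rna_allele_fraction
            if carrier:
                edits[p.pos] = p.alt
            if (carrier or p.alt is None) and rng.random() < p.plant.ir_penetrance:
                retained.add(p.intron)
        blocks = _blocks_with_retained(model, retained) if retained else normal_blocks
        template = _template_from_blocks(seq_codes, blocks, edits)
        if len(template) <= rl:
            start = 0
        else:
            start = int(rng.integers(0, len(template) - rl + 1))
        seq = _apply_errors(rng, template[start : start + rl], cfg.error_rate)
        rblocks = _blocks_for_slice(blocks, start, min(rl, len(template)))
        reads.append(
            _ReadTruth(
                chrom=model.chrom,
                start=rblocks[0][0],
                blocks=rblocks,
                seq=seq,
                reverse=bool(rng.integers(0, 2)),
            )
        )
    return reads


def _dna_reads(rng, cfg, model, seq_codes, plants, tumor: bool):
    rl = cfg.read_length
    chrom_len = len(seq_codes)
    n_reads = max(1, int(round(cfg.dna_depth * chrom_len / rl)))
    present = [
        p
        for p in plants
        if p.alt is not None
        and (p.plant.status == "germline" or (tumor and p.plant.status == "somatic"))
    ]
    reads = []
    for _ in range(n_reads):
        start = int(rng.integers(0, chrom_len - rl + 1))
        edits = {
            p.pos: p.alt for p in present if rng.random() < p.plant.dna_vaf
        }
        template = _template_from_blocks(seq_codes, ((start, start + rl),), edits)
        seq = _apply_errors(rng, template, cfg.error_rate)
        reads.append(
            _ReadTruth(
                chrom=model.chrom,
                start=start,
                blocks=((start, start + rl),),
                seq=seq,
                reverse=bool(rng.integers(0, 2)),
            )
        )
    return reads


def _write_bam(path: str, reads: list[_ReadTruth], contigs: dict[str, int], prefix: str):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    order = {name: i for i, name in enumerate(contigs)}
    reads = sorted(reads, key=lambda r: (order[r.chrom], r.start))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, rt in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"{prefix}{i + 1}"
            a.reference_id = order[rt.chrom]
            a.reference_start = rt.start
            a.mapping_quality = 60
            a.flag = 16 if rt.reverse else 0
            cigar = []
            prev_end = None
            for s, e in rt.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))
                cigar.append((0, e - s))
                prev_end = e
            a.cigartuples = cigar
            a.query_sequence = rt.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rt.seq))
            bam.write(a)
    pysam.index(path)


def export_fastq(bam_path: str, fastq_path: str):
    """Dump simulated reads as FASTQ for use with a real aligner."""
    with pysam.AlignmentFile(bam_path) as bam, open(fastq_path, "w") as fh:
        for read in bam.fetch(until_eof=True):
            seq = read.query_sequence
            qual = "I" * len(seq)
            if read.is_reverse:
                seq = reverse_complement(seq)
            fh.write(f"@{read.query_name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# truth helpers (plain arithmetic over emitted read blocks)

def _read_spans_boundary(blocks, boundary: int, span: int) -> bool:
    return any(s <= boundary - span and e >= boundary + span for s, e in blocks)


def _read_splices_at(blocks, boundary: int, intronic_right: bool) -> bool:
    for (s1, e1), (s2, _) in zip(blocks, blocks[1:]):
        if intronic_right and e1 == boundary:
            return True
        if not intronic_right and s2 == boundary:
            return True
    return False


def _boundary_truth_counts(reads, regions, span: int = 10):
    counts = []
    for region in regions:
        ir = spliced = 0
        for rt in reads:
            if rt.chrom != region.chrom:
                continue
            if _read_splices_at(rt.blocks, region.boundary, region.intronic_right):
                exonic_base = (
                    region.boundary - 1 if region.intronic_right else region.boundary
                )
                if any(s <= exonic_base < e for s, e in rt.blocks):
                    spliced += 1
            elif _read_spans_boundary(rt.blocks, region.boundary, span):
                ir += 1
        counts.append(
            {
                "chrom": region.chrom,
                "boundary": region.boundary,
                "side": region.side,
                "strand": region.strand,
                "ir_reads": ir,
                "spliced_reads": spliced,
            }
        )
    return counts


def _translate_consequence(model: TranscriptModel, intron, chrom_seq) -> dict:
    """Direct codon walk over the intron-retained mRNA (truth oracle)."""
    i = model.introns.index(intron)
    exons = (
        model.exons[:i]
        + ((model.exons[i][0], model.exons[i + 1][1]),)
        + model.exons[i + 2 :]
    )
    seq = "".join(_to_str(chrom_seq[s:e]) for s, e in exons)
    if model.strand == "-":
        seq = reverse_complement(seq)
        exon_list = exons[::-1]
    else:
        exon_list = exons

    def g2t(gpos):
        off = 0
        for s, e in exon_list:
            if s <= gpos < e:
                return off + (gpos - s if model.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    if model.strand == "+":
        cds_s, cds_e = g2t(model.cds_start), g2t(model.cds_end - 1) + 1
    else:
        cds_s, cds_e = g2t(model.cds_end - 1), g2t(model.cds_start) + 1
    stops = {"TAA", "TAG", "TGA"}
    ptc = None
    for p in range(cds_s, len(seq) - 2, 3):
        if seq[p : p + 3] in stops:
            if p < cds_e - 3:
                ptc = p
            break
    lengths = [e - s for s, e in exon_list]
    last_junction = sum(lengths[:-1]) if len(lengths) > 1 else None
    if ptc is None:
        nmd = "not_applicable"
    elif last_junction is not None and ptc < last_junction - 50:
        nmd = "sensitive"
    else:
        nmd = "insensitive"
    return {
        "ptc_created": ptc is not None,
        "ptc_mrna_pos": ptc,
        "last_junction_mrna_pos": last_junction,
        "nmd_class": nmd,
    }


# ---------------------------------------------------------------------------
# side tables

def _write_af_table(path: str, resolved, models, chrom_seqs, rng):
    rows = []
    for rp in resolved:
        if rp.alt is None:
            continue
        rows.append((rp.region.chrom, rp.pos + 1, rp.ref, rp.alt, 0.0001))
    # a couple of common decoys away from planted positions
    for model in models[: min(3, len(models))]:
        pos = model.exons[0][0] + 5
        if any(r.pos == pos for r in resolved):
            continue
        ref = _to_str(chrom_seqs[model.chrom][pos : pos + 1])
        rows.append((model.chrom, pos + 1, ref, _ALT_OF[ref], 0.02))
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_toy_clinvar(path: str, resolved, models, contigs):
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">',
        '##INFO=<ID=MC,Number=.,Type=String,Description="Molecular consequence">',
        '##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="Review status">',
        '##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene symbol:id">',
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, rp in enumerate(resolved):
        if rp.alt is None:
            continue
        model = models[rp.plant.gene_index]
        kind = i % 3
        if kind == 0:  # exact match
            pos, ref, alt = rp.pos + 1, rp.ref, rp.alt
            mc = (
                "SO:0001575|splice_donor_variant"
                if rp.region.side == DONOR
                else "SO:0001574|splice_acceptor_variant"
            )
        elif kind == 1:  # same splice site, different position
            other = next(
                p for p in range(rp.region.window[0], rp.region.window[1]) if p != rp.pos
            )
            pos, ref, alt = other + 1, "N", "A"
            mc = (
                "SO:0001575|splice_donor_variant"
                if rp.region.side == DONOR
                else "SO:0001574|splice_acceptor_variant"
            )
        else:  # truncating in the same gene
            pos = model.exons[0][0] + 20
            ref, alt = "N", "T"
            mc = "SO:0001587|nonsense"
        lines.append(
            f"{model.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t"
            f"CLNSIG=Pathogenic;MC={mc};"
            f"CLNREVSTAT=criteria_provided,_multiple_submitters,_no_conflicts;"
            f"GENEINFO={model.gene_symbol}:{1000 + rp.plant.gene_index}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# entry points

def simulate_scene(cfg: SimulationConfig, outdir: str) -> Scene:
    """Generate a full scene under ``outdir``; deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(outdir, exist_ok=True)
    models = []
    chrom_seqs: dict[str, np.ndarray] = {}
    for g in range(cfg.n_genes):
        model, seq = _build_gene(rng, cfg, g)
        models.append(model)
        chrom_seqs[model.chrom] = seq
    resolved = _resolve_plants(cfg, models, chrom_seqs)
    by_gene: dict[int, list[_ResolvedPlant]] = {}
    for rp in resolved:
        by_gene.setdefault(rp.plant.gene_index, []).append(rp)
    for gene_index, plist in by_gene.items():
        if len(plist) > 1 and len({p.intron for p in plist}) != len(plist):
            raise ValueError("at most one plant per intron per gene")

    reference = os.path.join(outdir, "reference.fa")
    with open(reference, "w") as fh:
        for model in models:
            fh.write(f">{model.chrom}\n")
            seq = _to_str(chrom_seqs[model.chrom])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(reference)

    annotation = os.path.join(outdir, "annotation.refgene.txt")
    write_refgene(models, annotation)

    contigs = {m.chrom: len(chrom_seqs[m.chrom]) for m in models}
    if cfg.read_seed is not None:
        rng = np.random.default_rng(cfg.read_seed)
    rna_reads: list[_ReadTruth] = []
    tumor_reads: list[_ReadTruth] = []
    normal_reads: list[_ReadTruth] = []
    for g, model in enumerate(models):
        plist = by_gene.get(g, [])
        rna_reads.extend(_gene_rna_reads(rng, cfg, model, chrom_seqs[model.chrom], plist))
        tumor_reads.extend(
            _dna_reads(rng, cfg, model, chrom_seqs[model.chrom], plist, tumor=True)
        )
        normal_reads.extend(
            _dna_reads(rng, cfg, model, chrom_seqs[model.chrom], plist, tumor=False)
        )
    rna_bam = os.path.join(outdir, "rna.bam")
    tumor_bam = os.path.join(outdir, "tumor.bam")
    normal_bam = os.path.join(outdir, "normal.bam")
    _write_bam(rna_bam, rna_reads, contigs, "rna")
    _write_bam(tumor_bam, tumor_reads, contigs, "tdna")
    _write_bam(normal_bam, normal_reads, contigs, "ndna")

    af_table = os.path.join(outdir, "af.tsv")
    _write_af_table(af_table, resolved, models, chrom_seqs, rng)
    clinvar_vcf = os.path.join(outdir, "clinvar.vcf")
    _write_toy_clinvar(clinvar_vcf, resolved, models, contigs)

    regions = build_splice_site_regions(models)
    truth_plants = []
    for rp in resolved:
        model = models[rp.plant.gene_index]
        entry = {
            "chrom": rp.region.chrom,
            "pos": rp.pos,
            "pos1": rp.pos + 1,
            "ref": rp.ref,
            "alt": rp.alt,
            "gene_symbol": model.gene_symbol,
            "transcript_id": model.transcript_id,
            "side": rp.region.side,
            "strand": rp.region.strand,
            "boundary": rp.region.boundary,
            "intron": list(rp.intron),
            "window_offset": rp.plant.window_offset,
            "dna_vaf": rp.plant.dna_vaf,
            "rna_vaf": rp.plant.rna_allele_fraction,
            "ir_penetrance": rp.plant.ir_penetrance,
            "status": rp.plant.status,
            "carriers": [cfg.sample_id],
            "consequence": _translate_consequence(
                model, rp.intron, chrom_seqs[model.chrom]
            ),
        }
        truth_plants.append(entry)
    truth = {
        "seed": cfg.seed,
        "sample_id": cfg.sample_id,
        "plants": truth_plants,
        "boundary_counts": _boundary_truth_counts(rna_reads, regions),
    }
    truth_json = os.path.join(outdir, "truth.json")
    with open(truth_json, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return Scene(
        outdir=outdir,
        reference=reference,
        annotation=annotation,
        rna_bam=rna_bam,
        tumor_bam=tumor_bam,
        normal_bam=normal_bam,
        af_table=af_table,
        clinvar_vcf=clinvar_vcf,
        truth_json=truth_json,
        models=models,
        regions=regions,
        truth=truth,
    )


def make_null_scene(cfg: SimulationConfig, outdir: str) -> Scene:
    """A scene with no planted variants (background error only)."""
    if cfg.plants:
        raise ValueError("null scene must not define plants")
    return simulate_scene(cfg, outdir)


def make_recovery_config(
    n_genes: int = 20,
    n_plants: int = 30,
    seed: int = 0,
    depth: float = 50.0,
    vaf_choices: Sequence[float] = (0.3, 0.4, 0.5),
    ir_penetrance: float = 1.0,
    error_rate: float = 0.001,
) -> SimulationConfig:
    """A planted-recovery study: ``n_plants`` essential-site variants spread
    over distinct introns of ``n_genes`` genes."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_genes=n_genes,
        exons_per_gene=(4, 5),
        depth=depth,
        error_rate=error_rate,
        seed=seed,
    )
    # enumerate (gene, intron) slots deterministically, then assign plants
    slots = [(g, i) for g in range(n_genes) for i in range(cfg.exons_per_gene[0] - 1)]
    if n_plants > len(slots):
        raise ValueError("more plants than available introns")
    chosen = rng.choice(len(slots), size=n_plants, replace=False)
    plants = []
    for j, slot in enumerate(sorted(int(c) for c in chosen)):
        g, i = slots[slot]
        side = DONOR if rng.random() < 0.7 else ACCEPTOR
        strand = "+" if g % 2 == 0 else "-"
        offset = int(rng.choice(ESSENTIAL_WINDOW_OFFSETS[(side, strand)]))
        plants.append(
            PlantedVariant(
                gene_index=g,
                intron_index=i,
                side=side,
                window_offset=offset,
                alt="auto",
                dna_vaf=0.5,
                rna_vaf=float(rng.choice(vaf_choices)),
                ir_penetrance=ir_penetrance,
                status="germline" if j % 2 == 0 else "somatic",
            )
        )
    cfg.plants = plants
    return cfg
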