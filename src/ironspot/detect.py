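"""The IRAV detector.

From a coordinate-sorted RNA-seq alignment, candidate variants are piled up
inside splice-site scan windows, every read at the affected boundary is
classified into one of four classes — splicing-junction positive/negative,
intron-retention positive/negative — by pairwise realignment against the
reference and alternative haplotypes, and a cascade of filters keeps only
variants whose presence tracks the retention reads:

  #IR_Pos >= 3
  #IR_Pos / (#IR_Pos + #IR_Neg) >= 0.9      (variant specific to retention)
  #IR_Pos / (#SJ_Neg + #IR_Pos) >= 0.1      (enough penetrance / VAF)
  at least one retention read covers >= 25 intronic bases
  motif score drop >= 2.5
  population allele frequency <= 0.01 (strictly greater is removed)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import Align

from . import scoring
from .regions import SpliceSiteRegion
from .scoring import SpliceModel, SpliceScoreDelta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectConfig:
    """Every threshold of the detector, at its published default."""

    min_var_reads: int = 3
    min_vaf: float = 0.05
    min_mapq: int = 20
    min_positions: int = 3
    edge_window: int = 5
    edge_rule: str = "outside"  # interior support required; "inside" inverts
    min_ir_pos: int = 3
    min_specificity: float = 0.9
    min_penetrance: float = 0.1
    min_intronic_cov: int = 25
    delta_threshold: float = 2.5
    max_af: float = 0.01
    realign_flank: int = 30
    match_score: float = 2.0
    mismatch_score: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


_EXCLUDE_FLAGS = (
    pysam.FSECONDARY | pysam.FSUPPLEMENTARY | pysam.FDUP | pysam.FUNMAP | pysam.FQCFAIL
)


def _read_ok(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (read.flag & _EXCLUDE_FLAGS) and read.mapping_quality >= min_mapq


@dataclass(frozen=True)
class CandidateVariant:
    """A putative variant in a scan window, with its pileup evidence.

    ``pos`` is 0-based; alleles are normalized (left-aligned, minimal).
    ``read_offsets`` holds the distinct positions of the variant within its
    supporting reads; ``edge_distances`` the per-supporting-read distance of
    the variant to the nearest read edge.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    var_count: int
    read_offsets: frozenset[int]
    edge_distances: frozenset[int]

    @property
    def vaf(self) -> float:
        return self.var_count / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ReadClassCounts:
    sj_pos: int
    sj_neg: int
    ir_pos: int
    ir_neg: int
    max_intronic_extent: int

    @property
    def specificity(self) -> float | None:
        denom = self.ir_pos + self.ir_neg
        return self.ir_pos / denom if denom else None

    @property
    def penetrance(self) -> float | None:
        denom = self.sj_neg + self.ir_pos
        return self.ir_pos / denom if denom else None


@dataclass(frozen=True)
class IravCall:
    """One detected intron-retention associated variant with its evidence."""

    variant: CandidateVariant
    region: SpliceSiteRegion
    counts: ReadClassCounts
    score_delta: SpliceScoreDelta | None
    population_af: float | None
    sample_id: str


# ---------------------------------------------------------------------------
# allele normalization

def normalize_variant(genome, chrom: str, pos: int, ref: str, alt: str):
    """Left-align and trim to the minimal representation (vt-style)."""
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) and len(alt) and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 0:
                    base = scoring._fetch(genome, chrom, 0, 1).upper()
                    ref, alt = base + ref, base + alt  # degenerate at contig start
                    break
                base = scoring._fetch(genome, chrom, pos - 1, pos).upper()
                pos -= 1
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# pileup

def pileup_candidates(
    alignments: pysam.AlignmentFile,
    regions: Sequence[SpliceSiteRegion],
    genome,
    config: DetectConfig = DetectConfig(),
) -> list[tuple[CandidateVariant, SpliceSiteRegion]]:
    """Pile up reads over scan windows and collect putative variants.

    SNVs and short indels supported by >= ``min_var_reads`` reads at
    >= ``min_vaf`` allele frequency are returned, each linked to the region
    whose window contains it.  Secondary/supplementary/duplicate/unmapped
    reads and reads below the MAPQ floor are excluded.
    """
    out: list[tuple[CandidateVariant, SpliceSiteRegion]] = []
    seen: set[tuple] = set()
    for region in regions:
        wstart, wend = region.window
        refwin = scoring._fetch(genome, region.chrom, max(0, wstart - 1), wend + 1).upper()
        ref_at = lambda p: refwin[p - max(0, wstart - 1)]
        # per-position: depth and per-allele support
        support: dict[tuple[int, str, str], list[tuple[int, int]]] = {}
        depth: dict[int, int] = {}
        for col in alignments.pileup(
            region.chrom,
            wstart,
            wend,
            truncate=True,
            min_base_quality=0,
            min_mapping_quality=config.min_mapq,
            flag_filter=_EXCLUDE_FLAGS,
            ignore_overlaps=False,
        ):
            pos = col.reference_pos
            refbase = ref_at(pos)
            n_cov = 0
            for pr in col.pileups:
                if pr.is_refskip:
                    continue
                read = pr.alignment
                qp = pr.query_position
                rlen = read.query_length or read.infer_query_length() or 0
                if not pr.is_del and qp is not None:
                    n_cov += 1
                    base = read.query_sequence[qp].upper()
                    if base != refbase and base in "ACGT":
                        support.setdefault((pos, refbase, base), []).append((qp, rlen))
                    if pr.indel > 0:
                        ins = read.query_sequence[qp + 1 : qp + 1 + pr.indel].upper()
                        key = (pos, refbase, refbase + ins)
                        support.setdefault(key, []).append((qp, rlen))
                    elif pr.indel < 0:
                        dlen = -pr.indel
                        dref = scoring._fetch(
                            genome, region.chrom, pos, pos + 1 + dlen
                        ).upper()
                        key = (pos, dref, dref[0])
                        support.setdefault(key, []).append((qp, rlen))
            depth[pos] = n_cov
        for (pos, ref, alt), obs in support.items():
            d = depth.get(pos, 0)
            if len(obs) < config.min_var_reads or d == 0:
                continue
            if len(obs) / d < config.min_vaf:
                continue
            npos, nref, nalt = normalize_variant(genome, region.chrom, pos, ref, alt)
            dedup_key = (region.key, region.chrom, npos, nref, nalt)
            if dedup_key in seen:
                continue
            seen.add(dedup_key)
            cand = CandidateVariant(
                chrom=region.chrom,
                pos=npos,
                ref=nref,
                alt=nalt,
                depth=d,
                var_count=len(obs),
                read_offsets=frozenset(qp for qp, _ in obs),
                edge_distances=frozenset(min(qp, rlen - 1 - qp) for qp, rlen in obs),
            )
            out.append((cand, region))
    out.sort(key=lambda cr: (cr[0].chrom, cr[0].pos, cr[0].ref, cr[0].alt))
    return out


def position_diversity_filter(
    cand: CandidateVariant,
    edge_window: int = 5,
    min_positions: int = 3,
    edge_rule: str = "outside",
) -> bool:
    """Alignment-artifact guard on the variant's positions within reads.

    Pass iff the variant is seen at >= ``min_positions`` distinct read
    offsets and the edge clause holds.  The default rule (``outside``)
    requires at least one supporting read to carry the variant in the read
    interior, at least ``edge_window`` bases away from both read edges —
    variants supported only at read edges are classic misalignment
    artifacts around exon-intron boundaries.  ``inside`` inverts the
    clause (at least one support within ``edge_window`` bases of an edge).
    """
    if len(cand.read_offsets) < min_positions:
        return False
    if not cand.edge_distances:
        return False
    if edge_rule == "inside":
        return min(cand.edge_distances) < edge_window
    if edge_rule == "outside":
        return max(cand.edge_distances) >= edge_window
    raise ValueError(f"unknown edge rule {edge_rule!r}")


# ---------------------------------------------------------------------------
# read classification

def _aligner(config: DetectConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    # fit alignment: read segment floats freely inside the haplotype window
    aligner.end_deletion_score = 0
    return aligner


def _coverage_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Contiguous reference intervals covered by the read (D merged, N splits)."""
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    cur_start = None
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference contiguously
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == 3:  # N splits coverage
            if cur_start is not None:
                blocks.append((cur_start, pos))
                cur_start = None
            pos += length
        # I, S, H, P do not consume reference
    if cur_start is not None:
        blocks.append((cur_start, pos))
    return blocks


def _splices_at(read: pysam.AlignedSegment, region: SpliceSiteRegion) -> bool:
    """True when the read has a reference skip whose edge sits exactly on
    the region's boundary, on the intronic side."""
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):
            pos += length
        elif op == 3:
            if region.intronic_right and pos == region.boundary:
                return True
            if not region.intronic_right and pos + length == region.boundary:
                return True
            pos += length
    return False


def _spanning_block(read: pysam.AlignedSegment, region: SpliceSiteRegion):
    for start, end in _coverage_blocks(read):
        if start < region.boundary < end:
            return (start, end)
    return None


def _query_segment(read: pysam.AlignedSegment, start: int, end: int) -> str:
    """Read bases aligned within reference window [start, end)."""
    qpos = [q for q, r in read.get_aligned_pairs(matches_only=True) if start <= r < end]
    if not qpos:
        return ""
    return read.query_sequence[min(qpos) : max(qpos) + 1]


def _haplotype_windows(genome, region, cand, flank: int) -> tuple[str, str, int]:
    b = region.boundary
    start = max(0, b - flank)
    end = b + flank
    refseg = scoring._fetch(genome, region.chrom, start, end).upper()
    p = cand.pos - start
    if p < 0 or p + len(cand.ref) > len(refseg):
        return refseg, refseg, start
    altseg = refseg[:p] + cand.alt + refseg[p + len(cand.ref) :]
    return refseg, altseg, start


def classify_reads(
    alignments: pysam.AlignmentFile,
    region: SpliceSiteRegion,
    cand: CandidateVariant,
    genome,
    config: DetectConfig = DetectConfig(),
) -> ReadClassCounts:
    """Partition reads at the boundary into the four evidence classes.

    Junction reads splice exactly at the region's boundary; retention reads
    align contiguously across it with >= 1 base on each side.  Each read is
    variant-positive iff its realignment score against the alternative
    haplotype strictly exceeds the reference haplotype score (ties count as
    negative).  Reads that neither splice here nor span the boundary are
    ignored.
    """
    aligner = _aligner(config)
    ref_hap, alt_hap, hap_start = _haplotype_windows(genome, region, cand, config.realign_flank)
    hap_end = hap_start + len(ref_hap)
    sj_pos = sj_neg = ir_pos = ir_neg = 0
    max_extent = 0
    for read in alignments.fetch(
        region.chrom, max(0, region.boundary - 1), region.boundary + 1
    ):
        if not _read_ok(read, config.min_mapq):
            continue
        spliced = _splices_at(read, region)
        block = None if spliced else _spanning_block(read, region)
        if not spliced and block is None:
            continue
        seg = _query_segment(read, hap_start, hap_end)
        if seg:
            ref_score = aligner.score(ref_hap, seg)
            alt_score = aligner.score(alt_hap, seg)
            positive = alt_score > ref_score
        else:
            positive = False
        if spliced:
            if positive:
                sj_pos += 1
            else:
                sj_neg += 1
        else:
            if positive:
                ir_pos += 1
                if region.intronic_right:
                    extent = block[1] - region.boundary
                else:
                    extent = region.boundary - block[0]
                max_extent = max(max_extent, extent)
            else:
                ir_neg += 1
    return ReadClassCounts(sj_pos, sj_neg, ir_pos, ir_neg, max_extent)


def cascade_filter(
    counts: ReadClassCounts,
    min_ir_pos: int = 3,
    min_specificity: float = 0.9,
    min_penetrance: float = 0.1,
    min_intronic_cov: int = 25,
) -> tuple[bool, dict[str, bool]]:
    """Apply the four read-evidence rules; all thresholds are inclusive."""
    spec = counts.specificity
    pen = counts.penetrance
    verdicts = {
        "ir_pos": counts.ir_pos >= min_ir_pos,
        "specificity": spec is not None and spec >= min_specificity,
        "penetrance": pen is not None and pen >= min_penetrance,
        "intronic_cov": counts.max_intronic_extent >= min_intronic_cov,
    }
    return all(verdicts.values()), verdicts


# ---------------------------------------------------------------------------
# population allele frequencies

def load_af_table(path: str) -> dict[tuple[str, int, str, str], float]:
    """Load an allele-frequency source.

    Accepts a 5-column TSV (chrom, pos[1-based], ref, alt, af) or a VCF with
    an AF INFO field.  Keys are (chrom, pos0, ref, alt) with 0-based pos.
    """
    table: dict[tuple[str, int, str, str], float] = {}
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                afs = rec.info.get("AF")
                if afs is None:
                    continue
                if not isinstance(afs, (tuple, list)):
                    afs = (afs,)
                for alt, af in zip(rec.alts or (), afs):
                    table[(rec.chrom, rec.start, rec.ref, alt)] = float(af)
        return table
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            chrom, pos, ref, alt, af = fields[:5]
            table[(chrom, int(pos) - 1, ref.upper(), alt.upper())] = float(af)
    return table


def population_af_filter(
    cand: CandidateVariant,
    af_source: Mapping[tuple[str, int, str, str], float],
    max_af: float = 0.01,
) -> tuple[bool, float | None]:
    """Pass unless the variant is common: fail iff AF > max_af (strict).
    Variants absent from the table pass with a missing AF."""
    af = af_source.get(cand.key)
    if af is None:
        return True, None
    return af <= max_af, af


# ---------------------------------------------------------------------------
# composition

def detect(
    alignments: pysam.AlignmentFile,
    regions: Sequence[SpliceSiteRegion],
    genome,
    model_donor: SpliceModel,
    model_acceptor: SpliceModel,
    af_source: Mapping[tuple[str, int, str, str], float],
    config: DetectConfig = DetectConfig(),
    sample_id: str = "sample",
    keep_filtered: bool = False,
):
    """Run the full detector on one sample.

    Returns a list of passing :class:`IravCall`, sorted by coordinate.  With
    ``keep_filtered`` a second list of (call, failed-rule-names) for
    candidates that reached read classification but failed the cascade is
    also returned (useful for VCF FILTER annotation).
    """
    calls: list[IravCall] = []
    rejected: list[tuple[IravCall, list[str]]] = []
    for cand, region in pileup_candidates(alignments, regions, genome, config):
        failed: list[str] = []
        if not position_diversity_filter(
            cand, config.edge_window, config.min_positions, config.edge_rule
        ):
            failed.append("position_diversity")
        counts = classify_reads(alignments, region, cand, genome, config)
        ok, verdicts = cascade_filter(
            counts,
            config.min_ir_pos,
            config.min_specificity,
            config.min_penetrance,
            config.min_intronic_cov,
        )
        failed.extend(name for name, v in verdicts.items() if not v)
        if failed and not keep_filtered:
            continue
        delta, delta_ok = None, True
        try:
            delta, delta_ok = scoring.delta_filter(
                model_donor, model_acceptor, region, genome,
                cand.pos, cand.ref, cand.alt, config.delta_threshold,
            )
        except ValueError:
            # normalization may shift an indel out of the scan window; score
            # at the nearest in-window anchor is not defined, treat as fail
            delta, delta_ok = None, False
        if not delta_ok:
            failed.append("delta_score")
        af_ok, af = population_af_filter(cand, af_source, config.max_af)
        if not af_ok:
            failed.append("common_af")
        call = IravCall(
            variant=cand,
            region=region,
            counts=counts,
            score_delta=delta,
            population_af=af,
            sample_id=sample_id,
        )
        if failed:
            rejected.append((call, failed))
        else:
            calls.append(call)
    calls.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt))
    if keep_filtered:
        return calls, rejected
    return calls


@dataclass(frozen=True)
class DistinctIrav:
    """Calls sharing genomic position and substitution pattern, counted once."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_ids: tuple[str, ...]
    calls: tuple[IravCall, ...]


def merge_distinct(calls: Iterable[IravCall]) -> list[DistinctIrav]:
    """Group calls from many samples by (chrom, pos, ref, alt)."""
    groups: dict[tuple, list[IravCall]] = {}
    for call in calls:
        groups.setdefault(call.variant.key, []).append(call)
    out = []
    for (chrom, pos, ref, alt), group in sorted(groups.items()):
        out.append(
            DistinctIrav(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                sample_ids=tuple(dict.fromkeys(c.sample_id for c in group)),
                calls=tuple(group),
            )
        )
    return out
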