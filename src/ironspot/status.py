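"""Genomic mutation status of an IRAV from tumor/matched-normal DNA.

The variant site is interrogated in both DNA alignments; reads are counted
as variant-supporting by the same pairwise-realignment rule the RNA
detector uses (restricted to contiguously aligned reads, as DNA reads are).
The evidence is then routed through a flowchart into one of five statuses:
germline, somatic, somatic-or-germline, ambiguous, or false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .detect import DetectConfig, _aligner, _coverage_blocks, _query_segment, _read_ok
from . import scoring

GERMLINE = "germline"
SOMATIC = "somatic"
SOMATIC_OR_GERMLINE = "somatic_or_germline"
AMBIGUOUS = "ambiguous"
FALSE_POSITIVE = "false_positive"

STATUSES = (GERMLINE, SOMATIC, SOMATIC_OR_GERMLINE, AMBIGUOUS, FALSE_POSITIVE)


@dataclass(frozen=True)
class DnaEvidence:
    tumor_depth: int
    tumor_var: int
    normal_depth: int
    normal_var: int

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_var / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_var / self.normal_depth if self.normal_depth else 0.0


@dataclass(frozen=True)
class StatusConfig:
    """Flowchart cut-offs; each side with depth below ``min_depth`` counts
    as inadequately covered."""

    min_depth: int = 8
    min_var: int = 3
    germline_vaf: float = 0.25
    max_normal_var_somatic: int = 1


@dataclass(frozen=True)
class StatusCall:
    status: str
    evidence: DnaEvidence
    config: StatusConfig


def _count_site(
    alignments: pysam.AlignmentFile,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genome,
    config: DetectConfig,
) -> tuple[int, int]:
    """(depth, variant reads) at a site by ref/alt-haplotype realignment."""
    aligner = _aligner(config)
    flank = config.realign_flank
    start = max(0, pos - flank)
    end = pos + max(len(ref), 1) + flank
    ref_hap = scoring._fetch(genome, chrom, start, end).upper()
    p = pos - start
    alt_hap = ref_hap[:p] + alt.upper() + ref_hap[p + len(ref) :]
    depth = var = 0
    var_end = pos + max(len(ref), 1)
    for read in alignments.fetch(chrom, pos, var_end):
        if not _read_ok(read, config.min_mapq):
            continue
        # contiguous coverage across the variant locus
        if not any(s <= pos and e >= var_end for s, e in _coverage_blocks(read)):
            continue
        depth += 1
        seg = _query_segment(read, start, end)
        if seg and aligner.score(alt_hap, seg) > aligner.score(ref_hap, seg):
            var += 1
    return depth, var


def collect_evidence(
    tumor_aln: pysam.AlignmentFile,
    normal_aln: pysam.AlignmentFile,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genome,
    config: DetectConfig = DetectConfig(),
) -> DnaEvidence:
    """Targeted allele counts for one variant in tumor and normal DNA.

    Sites without coverage record zero depth.
    """
    t_depth, t_var = _count_site(tumor_aln, chrom, pos, ref, alt, genome, config)
    n_depth, n_var = _count_site(normal_aln, chrom, pos, ref, alt, genome, config)
    return DnaEvidence(t_depth, t_var, n_depth, n_var)


def classify_status(evidence: DnaEvidence, cfg: StatusConfig = StatusConfig()) -> StatusCall:
    """Route DNA evidence through the status flowchart.

    The branches, in order: both sides under-covered -> ambiguous; adequate
    coverage but no variant evidence on either side -> false positive;
    normal VAF at germline levels -> germline; tumor evidence with a clean,
    well-covered normal -> somatic; tumor evidence with an under-covered
    normal -> somatic or germline; anything else -> ambiguous.
    """
    t_ok = evidence.tumor_depth >= cfg.min_depth
    n_ok = evidence.normal_depth >= cfg.min_depth
    if not t_ok and not n_ok:
        status = AMBIGUOUS
    elif (
        t_ok
        and n_ok
        and evidence.tumor_var < cfg.min_var
        and evidence.normal_var < cfg.min_var
    ):
        status = FALSE_POSITIVE
    elif (
        n_ok
        and evidence.normal_var >= cfg.min_var
        and evidence.normal_vaf >= cfg.germline_vaf
    ):
        status = GERMLINE
    elif (
        evidence.tumor_var >= cfg.min_var
        and n_ok
        and evidence.normal_var <= cfg.max_normal_var_somatic
    ):
        status = SOMATIC
    elif evidence.tumor_var >= cfg.min_var and not n_ok:
        status = SOMATIC_OR_GERMLINE
    else:
        status = AMBIGUOUS
    return StatusCall(status=status, evidence=evidence, config=cfg)
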