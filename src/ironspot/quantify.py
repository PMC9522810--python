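"""Quantification of intron retention at exon-intron boundaries.

A read counts toward retention when it aligns contiguously over at least
10 bases on both sides of the boundary; a read counts as normally spliced
when it splices at the junction and covers the last exonic base.  The
quantification is variant-agnostic.  Two summary ratios are provided: the
plain retention fraction ir/(ir+spliced) and the +1-smoothed local ratio
ir/(spliced+ir+1) used for local intron-retention comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .detect import DetectConfig, _coverage_blocks, _read_ok, _splices_at
from .regions import SpliceSiteRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundaryCount:
    region: SpliceSiteRegion
    ir_reads: int
    spliced_reads: int

    @property
    def ir_ratio(self) -> float | None:
        denom = self.ir_reads + self.spliced_reads
        return self.ir_reads / denom if denom else None

    @property
    def local_ir_ratio_value(self) -> float:
        return local_ir_ratio(self.ir_reads, self.spliced_reads)


def local_ir_ratio(exon_to_intron_reads: int, spliced: int) -> float:
    """The +1-smoothed local retention ratio e/(s+e+1), bounded in [0,1)."""
    if exon_to_intron_reads < 0 or spliced < 0:
        raise ValueError("read counts must be non-negative")
    return exon_to_intron_reads / (spliced + exon_to_intron_reads + 1)


def _covers_contiguously(read, start: int, end: int) -> bool:
    return any(s <= start and e >= end for s, e in _coverage_blocks(read))


def _covers_last_exonic_base(read, region: SpliceSiteRegion) -> bool:
    exonic_base = region.boundary - 1 if region.intronic_right else region.boundary
    return any(s <= exonic_base < e for s, e in _coverage_blocks(read))


def count_boundary(
    alignments: pysam.AlignmentFile,
    region: SpliceSiteRegion,
    span: int = 10,
    config: DetectConfig = DetectConfig(),
) -> BoundaryCount:
    """Count retention and spliced reads at one boundary.

    Retention requires contiguous alignment over [boundary-span,
    boundary+span); spliced requires a junction exactly at the boundary with
    the adjacent exonic base covered.  Read exclusion matches the detector.
    """
    b = region.boundary
    ir = spliced = 0
    for read in alignments.fetch(region.chrom, max(0, b - span), b + span):
        if not _read_ok(read, config.min_mapq):
            continue
        if _splices_at(read, region):
            if _covers_last_exonic_base(read, region):
                spliced += 1
        elif _covers_contiguously(read, b - span, b + span):
            ir += 1
    return BoundaryCount(region=region, ir_reads=ir, spliced_reads=spliced)


def ir_matrix(
    alignments_by_sample: Mapping[str, str],
    regions: Sequence[SpliceSiteRegion],
    span: int = 10,
    config: DetectConfig = DetectConfig(),
) -> pd.DataFrame:
    """Long-form table of boundary counts per sample x region.

    ``alignments_by_sample`` maps sample id to an indexed BAM/CRAM path.
    Boundaries without coverage get missing (NaN) ratios, not zero.  A
    sample whose alignment fails to load is skipped with an error logged.
    """
    rows = []
    for sample, path in alignments_by_sample.items():
        try:
            aln = pysam.AlignmentFile(path)
        except (OSError, ValueError) as exc:
            logger.error("sample %s failed to load (%s); skipped", sample, exc)
            continue
        with aln:
            for region in regions:
                bc = count_boundary(aln, region, span, config)
                rows.append(
                    {
                        "sample": sample,
                        "chrom": region.chrom,
                        "boundary": region.boundary,
                        "side": region.side,
                        "strand": region.strand,
                        "ir_reads": bc.ir_reads,
                        "spliced_reads": bc.spliced_reads,
                        "ir_ratio": bc.ir_ratio,
                        "local_ir_ratio": bc.local_ir_ratio_value,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "boundary", "side", "strand",
                 "ir_reads", "spliced_reads", "ir_ratio", "local_ir_ratio"],
    )


def build_control_profile(matrix: pd.DataFrame) -> dict[tuple[str, int, str, str], list[float]]:
    """Turn an :func:`ir_matrix` table into a control-panel profile.

    Missing ratios (no coverage) contribute 0: an uncovered boundary shows
    no innate retention.
    """
    profile: dict[tuple[str, int, str, str], list[float]] = {}
    for (chrom, boundary, side, strand), grp in matrix.groupby(
        ["chrom", "boundary", "side", "strand"], sort=True
    ):
        profile[(chrom, int(boundary), side, strand)] = [
            0.0 if pd.isna(x) else float(x) for x in grp["ir_ratio"]
        ]
    return profile


def write_boundary_table(counts: Sequence[BoundaryCount], path: str):
    with open(path, "w") as fh:
        fh.write(
            "chrom\tboundary\tside\tstrand\tir_reads\tspliced_reads\t"
            "ir_ratio\tlocal_ir_ratio\n"
        )
        for bc in counts:
            r = bc.region
            ratio = "NA" if bc.ir_ratio is None else f"{bc.ir_ratio:.6g}"
            fh.write(
                f"{r.chrom}\t{r.boundary}\t{r.side}\t{r.strand}\t"
                f"{bc.ir_reads}\t{bc.spliced_reads}\t{ratio}\t"
                f"{bc.local_ir_ratio_value:.6g}\n"
            )
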