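"""Transcript models and splice-site scan windows.

A splice-site *scan window* is the short stretch of sequence around an
exon-intron boundary in which a variant can plausibly disrupt the splice
motif: 3 exonic + 6 intronic bases at donor sites, 6 intronic + 1 exonic
base at acceptor sites.  Windows are built strand-aware from a transcript
annotation, deduplicated across isoforms sharing a boundary, purged of
windows buried inside other genes' exons, and filtered against a control
panel of samples with innate intron retention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DONOR = "donor"
ACCEPTOR = "acceptor"

# window geometry (bases on each side of the boundary, in transcript sense)
DONOR_EXONIC = 3
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 6
ACCEPTOR_EXONIC = 1
DONOR_WINDOW_LEN = DONOR_EXONIC + DONOR_INTRONIC
ACCEPTOR_WINDOW_LEN = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: exon structure, CDS span and strand.

    Coordinates are 0-based, half-open.  ``cds_start == cds_end`` marks a
    non-coding transcript (the refGene convention).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise AnnotationError(f"{self.transcript_id}: exons unsorted/overlapping")
            prev_end = end
        if self.cds_start > self.cds_end:
            raise AnnotationError(f"{self.transcript_id}: cds_start > cds_end")

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class SpliceSiteRegion:
    """One donor/acceptor scan window tied to an exon-intron boundary.

    ``boundary`` is the junction coordinate itself (0-based, half-open
    convention): for each side it equals either the intron's genomic start
    or its genomic end.  ``intronic_right`` says on which genomic side of
    the boundary the intron lies.
    """

    chrom: str
    boundary: int
    side: str
    strand: str
    window: tuple[int, int]
    intron: tuple[int, int]
    transcript_ids: tuple[str, ...]

    def __post_init__(self):
        wlen = self.window[1] - self.window[0]
        expected = DONOR_WINDOW_LEN if self.side == DONOR else ACCEPTOR_WINDOW_LEN
        if wlen != expected:
            raise ValueError(f"{self.side} window must span {expected} bases, got {wlen}")
        if not (self.window[0] < self.boundary < self.window[1]):
            raise ValueError("window must straddle the boundary")

    @property
    def transcript_id(self) -> str:
        return ",".join(self.transcript_ids)

    @property
    def intronic_right(self) -> bool:
        """True when the intron lies genomically to the right of the boundary."""
        return self.boundary == self.intron[0]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.boundary, self.side, self.strand)

    def contains(self, pos: int) -> bool:
        return self.window[0] <= pos < self.window[1]


# ---------------------------------------------------------------------------
# annotation parsing

def _parse_refgene(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            # UCSC refGene has 16 columns starting with `bin`; tolerate the
            # 15-column variant without it.
            if len(fields) == 16:
                fields = fields[1:]
            if len(fields) < 11:
                raise AnnotationError(f"{path}:{lineno}: expected >= 15 columns")
            try:
                name, chrom, strand = fields[0], fields[1], fields[2]
                cds_start, cds_end = int(fields[5]), int(fields[6])
                starts = [int(x) for x in fields[8].rstrip(",").split(",")]
                ends = [int(x) for x in fields[9].rstrip(",").split(",")]
                gene = fields[11] if len(fields) > 11 else name
            except (ValueError, IndexError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(starts) != len(ends):
                raise AnnotationError(f"{path}:{lineno}: exonStarts/exonEnds mismatch")
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_symbol=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(zip(starts, ends)),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    return models


def _parse_gtf(path: str) -> list[TranscriptModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # malformed file
        raise AnnotationError(f"{path}: failed to parse as GTF ({exc})") from exc
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene)
    for feature in db.all_features():
        if feature.featuretype not in ("exon", "CDS"):
            continue
        tids = feature.attributes.get("transcript_id")
        if not tids:
            raise AnnotationError(f"{path}: {feature.featuretype} missing transcript_id")
        tid = tids[0]
        gene = (feature.attributes.get("gene_name")
                or feature.attributes.get("gene_id") or [tid])[0]
        meta.setdefault(tid, (feature.seqid, feature.strand, gene))
        iv = (feature.start - 1, feature.end)  # GTF is 1-based inclusive
        (exons if feature.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, (chrom, strand, gene) in meta.items():
        exon_ivs = sorted(exons.get(tid, []))
        if not exon_ivs:
            logger.warning("transcript %s has no exon features; skipped", tid)
            continue
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        else:
            cds_start = cds_end = exon_ivs[0][0]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=gene,
                chrom=chrom,
                strand=strand,
                exons=tuple(exon_ivs),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def read_annotation(path: str, dialect: str = "refgene") -> list[TranscriptModel]:
    """Read a transcript annotation into :class:`TranscriptModel` records.

    ``dialect`` is ``"refgene"`` (UCSC refGene tab layout, 15 or 16 columns)
    or ``"gtf"`` (minimal GTF with exon/CDS features).
    """
    if dialect == "refgene":
        models = _parse_refgene(path)
    elif dialect == "gtf":
        models = _parse_gtf(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if not models:
        logger.warning("annotation %s yielded no transcripts", path)
    return models


# ---------------------------------------------------------------------------
# window construction

def _regions_for_model(model: TranscriptModel) -> Iterable[SpliceSiteRegion]:
    for i, (istart, iend) in enumerate(model.introns):
        left_exon = model.exons[i]
        right_exon = model.exons[i + 1]
        if model.strand == "+":
            donor_boundary, donor_exon = istart, left_exon
            donor_window = (istart - DONOR_EXONIC, istart + DONOR_INTRONIC)
            acc_boundary, acc_exon = iend, right_exon
            acc_window = (iend - ACCEPTOR_INTRONIC, iend + ACCEPTOR_EXONIC)
        else:
            donor_boundary, donor_exon = iend, right_exon
            donor_window = (iend - DONOR_INTRONIC, iend + DONOR_EXONIC)
            acc_boundary, acc_exon = istart, left_exon
            acc_window = (istart - ACCEPTOR_EXONIC, istart + ACCEPTOR_INTRONIC)
        if donor_exon[1] - donor_exon[0] >= DONOR_EXONIC:
            yield SpliceSiteRegion(
                model.chrom, donor_boundary, DONOR, model.strand,
                donor_window, (istart, iend), (model.transcript_id,),
            )
        else:
            logger.warning(
                "%s intron %d: exon shorter than donor window part; region skipped",
                model.transcript_id, i,
            )
        if acc_exon[1] - acc_exon[0] >= ACCEPTOR_EXONIC:
            yield SpliceSiteRegion(
                model.chrom, acc_boundary, ACCEPTOR, model.strand,
                acc_window, (istart, iend), (model.transcript_id,),
            )
        else:
            logger.warning(
                "%s intron %d: exon shorter than acceptor window part; region skipped",
                model.transcript_id, i,
            )


def build_splice_site_regions(models: Sequence[TranscriptModel]) -> list[SpliceSiteRegion]:
    """Build scan windows for every internal exon-intron boundary.

    Regions from isoforms sharing (chrom, boundary, side, strand) are merged
    into one, accumulating transcript ids.  Single-exon models contribute
    nothing.
    """
    merged: dict[tuple, SpliceSiteRegion] = {}
    for model in models:
        for region in _regions_for_model(model):
            prev = merged.get(region.key)
            if prev is None:
                merged[region.key] = region
            else:
                tids = prev.transcript_ids + tuple(
                    t for t in region.transcript_ids if t not in prev.transcript_ids
                )
                # keep the shorter intron when isoforms disagree on the far edge
                intron = min(prev.intron, region.intron, key=lambda iv: iv[1] - iv[0])
                merged[region.key] = replace(prev, transcript_ids=tids, intron=intron)
    return sorted(merged.values(), key=lambda r: (r.chrom, r.boundary, r.side))


def exclude_exon_overlapped(
    regions: Sequence[SpliceSiteRegion], models: Sequence[TranscriptModel]
) -> list[SpliceSiteRegion]:
    """Drop regions whose window lies completely inside an exon of another
    transcript.  Partial overlap, or containment only in the region's own
    transcripts, keeps the region."""
    trees: dict[str, IntervalTree] = {}
    for model in models:
        tree = trees.setdefault(model.chrom, IntervalTree())
        for start, end in model.exons:
            tree.addi(start, end, model.transcript_id)
    kept = []
    for region in regions:
        tree = trees.get(region.chrom)
        buried = False
        if tree is not None:
            for iv in tree.overlap(*region.window):
                if (
                    iv.begin <= region.window[0]
                    and iv.end >= region.window[1]
                    and iv.data not in region.transcript_ids
                ):
                    buried = True
                    break
        if not buried:
            kept.append(region)
    return kept


# ---------------------------------------------------------------------------
# control panel

ControlPanelProfile = Mapping[tuple[str, int, str, str], Sequence[float]]
"""Per-region vectors of intron-retention fractions across control samples,
keyed by (chrom, boundary, side, strand)."""


def filter_by_control_panel(
    regions: Sequence[SpliceSiteRegion],
    profile: ControlPanelProfile,
    frac_thresh: float = 0.05,
    n_thresh: int = 8,
) -> list[SpliceSiteRegion]:
    """Remove regions with innate intron retention in the control panel.

    A region is removed iff at least ``n_thresh`` control samples show an
    intron-retention fraction >= ``frac_thresh`` at it.  Regions missing
    from the profile are kept with a warning (treated as all-zero).
    """
    kept = []
    for region in regions:
        fracs = profile.get(region.key)
        if fracs is None:
            logger.warning("region %s absent from control profile; kept", region.key)
            kept.append(region)
            continue
        n_high = sum(1 for f in fracs if f >= frac_thresh)
        if n_high < n_thresh:
            kept.append(region)
    return kept


def read_control_profile(path: str) -> dict[tuple[str, int, str, str], list[float]]:
    """Read a control-panel profile TSV: chrom, boundary, side, strand,
    then one fraction column per control sample."""
    profile: dict[tuple[str, int, str, str], list[float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError(f"{path}: expected header starting with 'chrom'")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            chrom, boundary, side, strand = fields[:4]
            fracs = [float(x) for x in fields[4:] if x not in ("", "NA")]
            profile[(chrom, int(boundary), side, strand)] = fracs
    return profile


def write_control_profile(profile: ControlPanelProfile, path: str, sample_ids=None):
    n = max((len(v) for v in profile.values()), default=0)
    if sample_ids is None:
        sample_ids = [f"control{i+1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("chrom\tboundary\tside\tstrand\t" + "\t".join(sample_ids) + "\n")
        for (chrom, boundary, side, strand), fracs in sorted(profile.items()):
            vals = "\t".join(f"{f:.6g}" for f in fracs)
            fh.write(f"{chrom}\t{boundary}\t{side}\t{strand}\t{vals}\n")


def write_regions_bed(regions: Sequence[SpliceSiteRegion], path: str):
    """Write retained scan windows as 6-column BED (name = transcript_id;side)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.window[0]}\t{r.window[1]}\t"
                f"{r.transcript_id};{r.side}\t0\t{r.strand}\n"
            )
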