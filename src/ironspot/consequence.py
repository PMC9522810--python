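"""Molecular consequence of an intron-retention variant.

For each call the longest annotated transcript harboring the affected
exon-intron boundary is chosen, the boundary is classified against the CDS
(5'UTR / coding / 3'UTR), the intron-retained mRNA is rebuilt, translation
in the annotated frame looks for a premature termination codon (PTC) ahead
of the original stop, and a PTC is classified as NMD-sensitive by the 50nt
rule: PTCs located more than 50 nt upstream of the last exon-exon junction
of the retained transcript trigger nonsense-mediated decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .regions import SpliceSiteRegion, TranscriptModel
from .scoring import _fetch, reverse_complement

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

UTR5 = "utr5"
CODING = "coding"
UTR3 = "utr3"
NONCODING = "noncoding"

NMD_SENSITIVE = "sensitive"
NMD_INSENSITIVE = "insensitive"
NMD_NA = "not_applicable"


@dataclass(frozen=True)
class ConsequenceResult:
    region_class: str
    ptc_created: bool
    ptc_mrna_pos: int | None
    last_junction_mrna_pos: int | None
    nmd_class: str


# ---------------------------------------------------------------------------
# transcript-coordinate helpers (all strand-aware)

def exons_in_tx_order(model: TranscriptModel) -> list[tuple[int, int]]:
    exons = list(model.exons)
    return exons if model.strand == "+" else exons[::-1]


def genomic_to_tx(model: TranscriptModel, gpos: int) -> int | None:
    """Transcript coordinate of an exonic genomic base, else None."""
    offset = 0
    for start, end in exons_in_tx_order(model):
        if start <= gpos < end:
            if model.strand == "+":
                return offset + (gpos - start)
            return offset + (end - 1 - gpos)
        offset += end - start
    return None


def cds_tx_span(model: TranscriptModel) -> tuple[int, int] | None:
    """CDS interval in transcript coordinates (half-open), or None."""
    if not model.is_coding:
        return None
    if model.strand == "+":
        s = genomic_to_tx(model, model.cds_start)
        e = genomic_to_tx(model, model.cds_end - 1)
    else:
        s = genomic_to_tx(model, model.cds_end - 1)
        e = genomic_to_tx(model, model.cds_start)
    if s is None or e is None:
        return None
    return s, e + 1


def mrna_sequence(model: TranscriptModel, genome) -> str:
    parts = [
        _fetch(genome, model.chrom, start, end).upper() for start, end in model.exons
    ]
    seq = "".join(parts)
    return seq if model.strand == "+" else reverse_complement(seq)


def retained_model(model: TranscriptModel, retained_intron: tuple[int, int]) -> TranscriptModel:
    """The transcript with one intron retained: its flanking exons merged.

    A zero-length interval (degenerate) returns the model unchanged.
    """
    istart, iend = retained_intron
    if iend == istart:
        return model
    introns = model.introns
    if (istart, iend) not in introns:
        raise ValueError(f"{retained_intron} is not an intron of {model.transcript_id}")
    i = introns.index((istart, iend))
    exons = (
        model.exons[:i]
        + ((model.exons[i][0], model.exons[i + 1][1]),)
        + model.exons[i + 2 :]
    )
    return replace(model, exons=exons)


def junction_positions(model: TranscriptModel) -> list[int]:
    """Exon-exon junction coordinates on the mRNA (position of the first
    base after each junction, in transcript order)."""
    positions = []
    offset = 0
    ordered = exons_in_tx_order(model)
    for start, end in ordered[:-1]:
        offset += end - start
        positions.append(offset)
    return positions


# ---------------------------------------------------------------------------
# operations

def choose_transcript(
    chrom: str, boundary: int, models: Sequence[TranscriptModel]
) -> TranscriptModel | None:
    """Longest transcript (summed exon length) harboring the boundary;
    ties break toward the lexicographically smaller transcript id."""
    candidates = [
        m
        for m in models
        if m.chrom == chrom and any(boundary in (iv[0], iv[1]) for iv in m.introns)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda m: (-m.exonic_length, m.transcript_id))


def classify_region(region: SpliceSiteRegion, model: TranscriptModel) -> str:
    """Class of the affected boundary relative to the CDS (strand-aware)."""
    if not model.is_coding:
        return NONCODING
    span = cds_tx_span(model)
    if span is None:
        return NONCODING
    exonic_base = region.boundary - 1 if region.intronic_right else region.boundary
    t = genomic_to_tx(model, exonic_base)
    if t is None:
        return NONCODING
    if t < span[0]:
        return UTR5
    if t >= span[1]:
        return UTR3
    return CODING


def ptc_scan(
    model: TranscriptModel,
    retained_intron: tuple[int, int],
    genome,
    region_class: str = CODING,
) -> ConsequenceResult:
    """Translate the intron-retained mRNA and look for a premature stop.

    Reports the first in-frame stop codon occurring strictly before the
    original termination codon on the retained transcript, and the position
    of the last exon-exon junction of the retained transcript (the retained
    intron's own junction no longer exists).
    """
    rmodel = retained_model(model, retained_intron)
    junctions = junction_positions(rmodel)
    last_junction = junctions[-1] if junctions else None
    if not model.is_coding:
        return ConsequenceResult(NONCODING, False, None, last_junction, NMD_NA)
    span = cds_tx_span(rmodel)
    if span is None:
        return ConsequenceResult(region_class, False, None, last_junction, NMD_NA)
    cds_start, cds_end = span
    if (cds_tx_span(model)[1] - cds_tx_span(model)[0]) % 3 != 0:
        logger.warning(
            "%s: CDS length not a multiple of 3; scanning in annotated frame",
            model.transcript_id,
        )
    mrna = mrna_sequence(rmodel, genome)
    original_stop = cds_end - 3
    ptc_pos = None
    for p in range(cds_start, len(mrna) - 2, 3):
        if mrna[p : p + 3] in STOP_CODONS:
            if p < original_stop:
                ptc_pos = p
            break
    created = ptc_pos is not None
    return ConsequenceResult(
        region_class=region_class,
        ptc_created=created,
        ptc_mrna_pos=ptc_pos,
        last_junction_mrna_pos=last_junction,
        nmd_class=nmd_50nt_class(ptc_pos, last_junction) if created else NMD_NA,
    )


def nmd_50nt_class(ptc_mrna_pos: int, last_junction_mrna_pos: int | None) -> str:
    """Sensitive iff the PTC lies strictly more than 50 nt upstream of the
    last exon-exon junction of the retained transcript."""
    if last_junction_mrna_pos is None:
        return NMD_INSENSITIVE
    return (
        NMD_SENSITIVE
        if ptc_mrna_pos < last_junction_mrna_pos - 50
        else NMD_INSENSITIVE
    )


def nmd_50nt(result: ConsequenceResult) -> str:
    if not result.ptc_created:
        raise ValueError("NMD class is defined only when a PTC is created")
    return nmd_50nt_class(result.ptc_mrna_pos, result.last_junction_mrna_pos)


def annotate_consequence(
    region: SpliceSiteRegion, models: Sequence[TranscriptModel], genome
) -> tuple[ConsequenceResult, TranscriptModel | None]:
    """Full consequence annotation for one call's region."""
    model = choose_transcript(region.chrom, region.boundary, models)
    if model is None:
        return ConsequenceResult(NONCODING, False, None, None, NMD_NA), None
    intron = next(
        iv for iv in model.introns if region.boundary in (iv[0], iv[1])
    )
    rclass = classify_region(region, model)
    if not model.is_coding:
        return ptc_scan(model, intron, genome, NONCODING), model
    return ptc_scan(model, intron, genome, rclass), model
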