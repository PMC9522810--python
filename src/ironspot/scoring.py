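"""Position-weight log-odds models for splice donor/acceptor motifs.

The detector requires that a candidate variant weaken the splice motif: the
motif score of the alternative allele must drop by at least 2.5 relative to
the reference allele.  The scorer here is an additive per-position log-odds
(log2) model with the classical MaxEntScan window geometry — donor 9-mer
(3 exonic + 6 intronic bases), acceptor 23-mer (20 intronic + 3 exonic
bases) — trained from annotated splice sites of the genome at hand.  The
scorer is pluggable: any object with a ``window_len`` for each side and a
``score(seq)`` method can stand in (e.g. true maximum-entropy tables loaded
from files).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .regions import ACCEPTOR, DONOR, SpliceSiteRegion

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_SCORE_EXONIC = 3
DONOR_SCORE_INTRONIC = 6
ACCEPTOR_SCORE_INTRONIC = 20
ACCEPTOR_SCORE_EXONIC = 3
WINDOW_LEN = {DONOR: DONOR_SCORE_EXONIC + DONOR_SCORE_INTRONIC,
              ACCEPTOR: ACCEPTOR_SCORE_INTRONIC + ACCEPTOR_SCORE_EXONIC}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpliceModel:
    """Per-position nucleotide log-odds table (log2) for one side."""

    side: str
    log_odds: np.ndarray  # shape (window_len, 4)
    background: np.ndarray  # shape (4,), sums to 1
    pseudocount: float

    def __post_init__(self):
        if self.log_odds.shape != (self.window_len, 4):
            raise ValueError("log-odds table must be window_len x 4")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    @property
    def window_len(self) -> int:
        return WINDOW_LEN[self.side]

    def score(self, seq: str) -> float:
        return score(self, seq)


@dataclass(frozen=True)
class SpliceScoreDelta:
    """Reference vs. alternative motif score; delta = ref - alt."""

    ref_score: float
    alt_score: float

    @property
    def delta(self) -> float:
        return self.ref_score - self.alt_score


def train_model(
    sites: Sequence[str],
    side: str,
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> SpliceModel:
    """Train a log-odds model from window sequences of annotated splice sites.

    log_odds[i][b] = log2((count[i][b] + pseudocount) / (n + 4*pseudocount))
                     - log2(background[b])

    Sequences of wrong length or with non-ACGT characters are rejected with
    a warning; at least 10 valid sequences are required.
    """
    wlen = WINDOW_LEN[side]
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
    counts = np.zeros((wlen, 4), dtype=float)
    n = 0
    for seq in sites:
        s = seq.upper()
        if len(s) != wlen or any(c not in _BASE_INDEX for c in s):
            logger.warning("rejected training sequence %r (length/alphabet)", seq)
            continue
        for i, c in enumerate(s):
            counts[i, _BASE_INDEX[c]] += 1
        n += 1
    if n < 10:
        raise ValueError(f"need >= 10 valid training sequences, got {n}")
    log_odds = np.log2((counts + pseudocount) / (n + 4 * pseudocount)) - np.log2(bg)
    return SpliceModel(side=side, log_odds=log_odds, background=bg, pseudocount=pseudocount)


def score(model: SpliceModel, seq: str) -> float:
    """Additive per-position log-odds score of a window sequence."""
    s = seq.upper()
    if len(s) != model.window_len:
        raise ValueError(f"sequence length {len(s)} != window length {model.window_len}")
    total = 0.0
    for i, c in enumerate(s):
        j = _BASE_INDEX.get(c)
        if j is None:
            raise ValueError(f"ambiguous base {c!r} at position {i}")
        total += float(model.log_odds[i, j])
    return total


# ---------------------------------------------------------------------------
# serialization: TSV table + JSON metadata sidecar

def save_model(model: SpliceModel, path: str):
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\n")
        for i in range(model.window_len):
            row = "\t".join(repr(float(x)) for x in model.log_odds[i])
            fh.write(f"{i}\t{row}\n")
    meta = {
        "side": model.side,
        "window_len": model.window_len,
        "units": "bits",
        "background": [float(x) for x in model.background],
        "pseudocount": model.pseudocount,
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def load_model(path: str) -> SpliceModel:
    with open(path + ".json") as fh:
        meta = json.load(fh)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["position", "A", "C", "G", "T"]:
            raise ValueError(f"{path}: unexpected model table header")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.append([float(x) for x in fields[1:5]])
    return SpliceModel(
        side=meta["side"],
        log_odds=np.asarray(rows, dtype=float),
        background=np.asarray(meta["background"], dtype=float),
        pseudocount=float(meta["pseudocount"]),
    )


# ---------------------------------------------------------------------------
# window extraction and the delta filter

def scoring_window_span(region: SpliceSiteRegion) -> tuple[int, int]:
    """Genomic interval of the scoring window for a region (strand-aware)."""
    b = region.boundary
    if region.side == DONOR:
        if region.strand == "+":
            return (b - DONOR_SCORE_EXONIC, b + DONOR_SCORE_INTRONIC)
        return (b - DONOR_SCORE_INTRONIC, b + DONOR_SCORE_EXONIC)
    if region.strand == "+":
        return (b - ACCEPTOR_SCORE_INTRONIC, b + ACCEPTOR_SCORE_EXONIC)
    return (b - ACCEPTOR_SCORE_EXONIC, b + ACCEPTOR_SCORE_INTRONIC)


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else reverse_complement(seq)


_ANCHOR_FLANK = 60


def extract_windows(
    genome, region: SpliceSiteRegion, pos: int, ref: str, alt: str
) -> tuple[str, str] | None:
    """Return (ref window, alt window) in transcript orientation.

    The alternative window is rebuilt from the alt haplotype re-anchored at
    the boundary: the exon-intron junction keeps its place and the window is
    read off the edited sequence around it, so indels shift flanking bases
    rather than the boundary itself.  Returns None when the window runs off
    the contig.
    """
    b = region.boundary
    chrom_len = _contig_length(genome, region.chrom)
    seg_start = b - _ANCHOR_FLANK
    seg_end = b + _ANCHOR_FLANK
    if seg_start < 0 or seg_end > chrom_len:
        # fall back to a clipped segment; window extraction below re-checks
        seg_start = max(0, seg_start)
        seg_end = min(chrom_len, seg_end)
    refseg = _fetch(genome, region.chrom, seg_start, seg_end).upper()
    b_ref = b - seg_start
    p = pos - seg_start
    if p < 0 or p + len(ref) > len(refseg):
        return None
    if refseg[p : p + len(ref)] != ref.upper():
        logger.warning(
            "reference allele mismatch at %s:%d (expected %s)", region.chrom, pos, ref
        )
    altseg = refseg[:p] + alt.upper() + refseg[p + len(ref) :]
    shift = len(alt) - len(ref)
    if p + len(ref) <= b_ref:
        b_alt = b_ref + shift
    elif p >= b_ref:
        b_alt = b_ref
    else:  # variant spans the boundary: anchor at the left edge of the edit
        b_alt = p + min(len(alt), b_ref - p)
    span = scoring_window_span(region)
    rel = (span[0] - b, span[1] - b)
    ref_w = refseg[b_ref + rel[0] : b_ref + rel[1]]
    alt_w = altseg[b_alt + rel[0] : b_alt + rel[1]]
    wlen = span[1] - span[0]
    if len(ref_w) != wlen or len(alt_w) != wlen or b_ref + rel[0] < 0 or b_alt + rel[0] < 0:
        return None
    return _oriented(ref_w, region.strand), _oriented(alt_w, region.strand)


def delta_filter(
    model_donor: SpliceModel,
    model_acceptor: SpliceModel,
    region: SpliceSiteRegion,
    genome,
    pos: int,
    ref: str,
    alt: str,
    threshold: float = 2.5,
) -> tuple[SpliceScoreDelta | None, bool]:
    """Score ref vs alt windows; pass iff the score drops by >= threshold.

    The variant must start inside the region's scan window.  A window that
    runs off the contig end fails with a warning.
    """
    if not region.contains(pos):
        raise ValueError(
            f"variant {region.chrom}:{pos} outside scan window {region.window}"
        )
    windows = extract_windows(genome, region, pos, ref, alt)
    if windows is None:
        logger.warning("scoring window off contig end at %s:%d; filtered", region.chrom, pos)
        return None, False
    model = model_donor if region.side == DONOR else model_acceptor
    delta = SpliceScoreDelta(ref_score=score(model, windows[0]),
                             alt_score=score(model, windows[1]))
    return delta, delta.delta >= threshold


# small adapters so both pysam.FastaFile and pyfaidx.Fasta work

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    if hasattr(genome, "fetch"):
        return genome.fetch(chrom, start, end)
    return str(genome[chrom][start:end])


def _contig_length(genome, chrom: str) -> int:
    if hasattr(genome, "get_reference_length"):
        return genome.get_reference_length(chrom)
    return len(genome[chrom])
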