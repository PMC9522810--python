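"""ClinVar-anchored pathogenicity tiers for IRAV calls.

Each call is placed in one of five tiers by its positional relationship to
registered pathogenic / likely-pathogenic (P/LP) variants:

  Tier 1  exact genomic position and substitution match;
  Tier 2  a P/LP splice-site variant in the same splice-site scan window;
  Tier 3  a P/LP truncating variant (nonsense / frameshift) within 30 bp of
          the affected boundary measured along the chosen transcript's mRNA;
  Tier 4  an NMD-sensitive call whose gene carries a P/LP truncating variant
          with solid review status;
  Tier 5  none of the above.

Drug-response flags use the identical rules with ClinVar's Drug_response
records as the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pysam

from .consequence import choose_transcript, genomic_to_tx
from .regions import SpliceSiteRegion, TranscriptModel

PATHOGENIC_CLNSIG = {
    "Pathogenic",
    "Likely_pathogenic",
    "Pathogenic/Likely_pathogenic",
}
DRUG_CLNSIG = {"Drug_response"}

SPLICE_MC = {"splice_donor_variant", "splice_acceptor_variant"}
TRUNCATING_MC = {"nonsense", "frameshift_variant"}

SOLID_REVIEW = {
    "criteria_provided,_multiple_submitters,_no_conflicts",
    "reviewed_by_expert_panel",
    "practice_guideline",
}

MATCH_EXACT = "exact"
MATCH_SPLICE_SITE = "same_splice_site"
MATCH_NEARBY_TRUNCATING = "nearby_truncating"
MATCH_SAME_GENE = "same_gene"
MATCH_NONE = "none"


@dataclass(frozen=True)
class ClinvarRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    clnsig: str
    mc: tuple[str, ...]
    review_status: str
    gene: str

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def is_pathogenic(self) -> bool:
        return self.clnsig in PATHOGENIC_CLNSIG

    @property
    def is_drug_response(self) -> bool:
        return self.clnsig in DRUG_CLNSIG


@dataclass(frozen=True)
class TierAssignment:
    tier: int
    matched_record: ClinvarRecord | None
    match_kind: str

    def __post_init__(self):
        if self.tier in (1, 2, 3, 4) and self.matched_record is None:
            raise ValueError("tiers 1-4 require a matched record")


def _mc_terms(raw) -> tuple[str, ...]:
    if raw is None:
        return ()
    if isinstance(raw, (tuple, list)):
        parts = []
        for item in raw:
            parts.extend(str(item).split(","))
    else:
        parts = str(raw).split(",")
    return tuple(p.split("|")[-1] for p in parts if p)


def load_clinvar(path: str) -> list[ClinvarRecord]:
    """Parse a ClinVar-style VCF (INFO: CLNSIG, MC, CLNREVSTAT or CLNSTAT,
    GENEINFO).  Raises if the CLNSIG key is not declared."""
    records = []
    with pysam.VariantFile(path) as vf:
        if "CLNSIG" not in vf.header.info:
            raise ValueError(f"{path}: VCF lacks the CLNSIG INFO key")
        for rec in vf:
            info = dict(rec.info)

            def _join(key):
                val = info.get(key)
                if val is None:
                    return ""
                if isinstance(val, (tuple, list)):
                    return ",".join(str(v) for v in val)
                return str(val)

            review = _join("CLNREVSTAT") or _join("CLNSTAT")
            geneinfo = _join("GENEINFO")
            gene = geneinfo.split(":")[0] if geneinfo else ""
            for alt in rec.alts or ():
                records.append(
                    ClinvarRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        clnsig=_join("CLNSIG"),
                        mc=_mc_terms(info.get("MC")),
                        review_status=review,
                        gene=gene,
                    )
                )
    return records


def _tx_distance_to_boundary(
    record: ClinvarRecord, region: SpliceSiteRegion, model: TranscriptModel
) -> int | None:
    """|mRNA distance| between a ClinVar variant and the affected boundary.

    Measured along the chosen transcript's exonic path; intronic ClinVar
    positions have no transcript coordinate and return None.
    """
    exonic_base = region.boundary - 1 if region.intronic_right else region.boundary
    t_boundary = genomic_to_tx(model, exonic_base)
    t_var = genomic_to_tx(model, record.pos0)
    if t_boundary is None or t_var is None:
        return None
    return abs(t_var - t_boundary)


def _assign(
    chrom: str,
    pos0: int,
    ref: str,
    alt: str,
    region: SpliceSiteRegion,
    gene: str,
    nmd_sensitive: bool,
    reference_set: Sequence[ClinvarRecord],
    models: Sequence[TranscriptModel],
    tx_window: int = 30,
) -> TierAssignment:
    model = choose_transcript(chrom, region.boundary, models)
    # rule 1: exact genomic position and substitution
    for rec in reference_set:
        if (rec.chrom, rec.pos0, rec.ref, rec.alt) == (chrom, pos0, ref, alt):
            return TierAssignment(1, rec, MATCH_EXACT)
    # rule 2: splice variant sharing the scan window
    for rec in reference_set:
        if rec.chrom == chrom and region.contains(rec.pos0) and set(rec.mc) & SPLICE_MC:
            return TierAssignment(2, rec, MATCH_SPLICE_SITE)
    # rule 3: truncating variant within 30 transcript-bp of the boundary
    if model is not None:
        for rec in reference_set:
            if rec.chrom != chrom or not set(rec.mc) & TRUNCATING_MC:
                continue
            dist = _tx_distance_to_boundary(rec, region, model)
            if dist is not None and dist <= tx_window:
                return TierAssignment(3, rec, MATCH_NEARBY_TRUNCATING)
    # rule 4: NMD-sensitive call, truncating variant in the same gene with
    # solid review status
    if nmd_sensitive and gene:
        for rec in reference_set:
            if (
                rec.gene == gene
                and set(rec.mc) & TRUNCATING_MC
                and rec.review_status in SOLID_REVIEW
            ):
                return TierAssignment(4, rec, MATCH_SAME_GENE)
    return TierAssignment(5, None, MATCH_NONE)


def assign_tier(
    chrom: str,
    pos0: int,
    ref: str,
    alt: str,
    region: SpliceSiteRegion,
    gene: str,
    nmd_sensitive: bool,
    clinvar: Sequence[ClinvarRecord],
    models: Sequence[TranscriptModel],
) -> TierAssignment:
    """Pathogenicity tier against P/LP ClinVar records; first rule wins."""
    reference = [r for r in clinvar if r.is_pathogenic]
    return _assign(chrom, pos0, ref, alt, region, gene, nmd_sensitive, reference, models)


def assign_drug_response(
    chrom: str,
    pos0: int,
    ref: str,
    alt: str,
    region: SpliceSiteRegion,
    gene: str,
    nmd_sensitive: bool,
    clinvar: Sequence[ClinvarRecord],
    models: Sequence[TranscriptModel],
) -> TierAssignment:
    """Same tier logic against the Drug_response reference set; tier 5
    means no relationship (no flag)."""
    reference = [r for r in clinvar if r.is_drug_response]
    return _assign(chrom, pos0, ref, alt, region, gene, nmd_sensitive, reference, models)
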