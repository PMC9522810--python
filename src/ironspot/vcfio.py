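"""VCF serialization of IRAV calls.

Calls are written as VCF 4.2 with the full evidence in INFO so a written
file parses back into identical :class:`IravCall` records.  Numeric
evidence that must survive a round trip exactly (VAF, motif scores,
population AF) is stored as Strings holding the full decimal repr; the
derived DSCORE and VAF keys are therefore exact, not float32-rounded.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pysam

from .detect import CandidateVariant, IravCall, ReadClassCounts
from .regions import SpliceSiteRegion
from .scoring import SpliceScoreDelta

FILTER_NAMES = (
    "position_diversity",
    "ir_pos",
    "specificity",
    "penetrance",
    "intronic_cov",
    "delta_score",
    "common_af",
)

_INFO_LINES = [
    ('IRPOS', '1', 'Integer', 'Intron-retention reads supporting the variant'),
    ('IRNEG', '1', 'Integer', 'Intron-retention reads without the variant'),
    ('SJPOS', '1', 'Integer', 'Spliced-junction reads supporting the variant'),
    ('SJNEG', '1', 'Integer', 'Spliced-junction reads without the variant'),
    ('MAXEXT', '1', 'Integer', 'Longest intronic run covered by a retention read'),
    ('DP', '1', 'Integer', 'Pileup depth at the variant position'),
    ('VC', '1', 'Integer', 'Variant-supporting reads in the pileup'),
    ('VAF', '1', 'String', 'Variant allele frequency (exact decimal)'),
    ('DSCORE', '1', 'String', 'Motif score reduction ref-alt (exact decimal)'),
    ('REFSC', '1', 'String', 'Reference-allele motif score'),
    ('ALTSC', '1', 'String', 'Alternative-allele motif score'),
    ('PAF', '1', 'String', 'Population allele frequency'),
    ('OFFSETS', '1', 'String', 'Distinct variant offsets within supporting reads'),
    ('EDGED', '1', 'String', 'Variant distances to nearest read edge'),
    ('REGION', '1', 'String', 'Splice-site region side|strand|boundary|window|intron|transcripts'),
    ('SAMPLE', '1', 'String', 'Sample identifier'),
    ('RCLASS', '1', 'String', 'Splice-site region class (utr5/coding/utr3/noncoding)'),
    ('PTC', '1', 'String', 'Premature termination codon transcript position, or none'),
    ('NMD', '1', 'String', 'NMD class by the 50nt rule'),
    ('MSTAT', '1', 'String', 'Genomic mutation status from tumor/normal DNA'),
    ('TDP', '1', 'Integer', 'Tumor DNA depth'), ('TVC', '1', 'Integer', 'Tumor DNA variant reads'),
    ('NDP', '1', 'Integer', 'Normal DNA depth'), ('NVC', '1', 'Integer', 'Normal DNA variant reads'),
    ('TIER', '1', 'Integer', 'ClinVar pathogenicity tier (1-5)'),
    ('TMATCH', '1', 'String', 'Kind of ClinVar positional match'),
    ('DRUGTIER', '1', 'Integer', 'Drug-response tier (1-4) when applicable'),
]


def _header(contigs: Mapping[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=ironspot"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    for fid, num, ftype, desc in _INFO_LINES:
        lines.append(f'##INFO=<ID={fid},Number={num},Type={ftype},Description="{desc}">')
    for fname in FILTER_NAMES:
        lines.append(f'##FILTER=<ID={fname},Description="Failed the {fname} rule">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def _region_tag(region: SpliceSiteRegion) -> str:
    tx = "&".join(region.transcript_ids)
    return (
        f"{region.side}|{region.strand}|{region.boundary}|"
        f"{region.window[0]}|{region.window[1]}|{region.intron[0]}|{region.intron[1]}|{tx}"
    )


def _parse_region_tag(chrom: str, tag: str) -> SpliceSiteRegion:
    side, strand, boundary, w0, w1, i0, i1, tx = tag.split("|")
    return SpliceSiteRegion(
        chrom=chrom,
        boundary=int(boundary),
        side=side,
        strand=strand,
        window=(int(w0), int(w1)),
        intron=(int(i0), int(i1)),
        transcript_ids=tuple(tx.split("&")),
    )


def _call_info(call: IravCall, extra: Mapping[str, object] | None = None) -> str:
    v, c = call.variant, call.counts
    items = [
        ("IRPOS", c.ir_pos), ("IRNEG", c.ir_neg),
        ("SJPOS", c.sj_pos), ("SJNEG", c.sj_neg),
        ("MAXEXT", c.max_intronic_extent),
        ("DP", v.depth), ("VC", v.var_count),
        ("VAF", repr(v.vaf)),
    ]
    if call.score_delta is not None:
        items += [
            ("DSCORE", repr(call.score_delta.delta)),
            ("REFSC", repr(call.score_delta.ref_score)),
            ("ALTSC", repr(call.score_delta.alt_score)),
        ]
    if call.population_af is not None:
        items.append(("PAF", repr(call.population_af)))
    items += [
        ("OFFSETS", "&".join(str(x) for x in sorted(v.read_offsets))),
        ("EDGED", "&".join(str(x) for x in sorted(v.edge_distances))),
        ("REGION", _region_tag(call.region)),
        ("SAMPLE", call.sample_id),
    ]
    if extra:
        items += [(k, val) for k, val in extra.items() if val is not None]
    return ";".join(f"{k}={val}" for k, val in items)


def write_calls_vcf(
    path: str,
    calls: Sequence[IravCall],
    contigs: Mapping[str, int],
    rejected: Sequence[tuple[IravCall, Sequence[str]]] = (),
    annotations: Mapping[tuple, Mapping[str, object]] | None = None,
):
    """Write passing calls (FILTER=PASS) and optionally rejected candidates
    (FILTER=failed rule names).  ``annotations`` maps a variant key to extra
    INFO entries (consequence, status, tiers)."""
    rows = [(call, ()) for call in calls] + [(c, tuple(f)) for c, f in rejected]
    rows.sort(key=lambda r: (r[0].variant.chrom, r[0].variant.pos, r[0].variant.ref,
                             r[0].variant.alt))
    with open(path, "w") as fh:
        fh.write(_header(contigs))
        for call, failed in rows:
            v = call.variant
            filt = ";".join(failed) if failed else "PASS"
            extra = (annotations or {}).get(v.key)
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t"
                f"{_call_info(call, extra)}\n"
            )


def read_calls_vcf(path: str):
    """Parse a VCF written by :func:`write_calls_vcf`.

    Returns a list of (IravCall, failed_filters, extra_info_dict).
    """
    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = dict(rec.info)
            cand = CandidateVariant(
                chrom=rec.chrom,
                pos=rec.start,
                ref=rec.ref,
                alt=rec.alts[0],
                depth=info["DP"],
                var_count=info["VC"],
                read_offsets=frozenset(
                    int(x) for x in str(info["OFFSETS"]).split("&") if x
                ),
                edge_distances=frozenset(
                    int(x) for x in str(info["EDGED"]).split("&") if x
                ),
            )
            counts = ReadClassCounts(
                sj_pos=info["SJPOS"], sj_neg=info["SJNEG"],
                ir_pos=info["IRPOS"], ir_neg=info["IRNEG"],
                max_intronic_extent=info["MAXEXT"],
            )
            delta = None
            if "REFSC" in info:
                delta = SpliceScoreDelta(
                    ref_score=float(info["REFSC"]), alt_score=float(info["ALTSC"])
                )
            call = IravCall(
                variant=cand,
                region=_parse_region_tag(rec.chrom, str(info["REGION"])),
                counts=counts,
                score_delta=delta,
                population_af=float(info["PAF"]) if "PAF" in info else None,
                sample_id=str(info["SAMPLE"]),
            )
            failed = tuple(f for f in rec.filter.keys() if f != "PASS")
            extra = {
                k: info[k]
                for k in ("RCLASS", "PTC", "NMD", "MSTAT", "TDP", "TVC", "NDP",
                          "NVC", "TIER", "TMATCH", "DRUGTIER")
                if k in info
            }
            out.append((call, failed, extra))
    return out
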