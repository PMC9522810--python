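# Methods

## Problem and model

A splice-disrupting variant at an exon–intron boundary leaves a read-level
signature in RNA-seq: reads that retain the intron align contiguously
across the boundary and carry the alternative allele, while normally
spliced reads carry the reference. `ironspot` calls a variant an IRAV when
this co-occurrence is strong enough to survive a cascade of filters. The
approach deliberately detects *qualitative* retention — variants creating
retention at boundaries that do not normally retain. Variants that merely
strengthen retention at an innately leaky splice site are outside the
model: such boundaries are removed up front by the control-panel filter,
and detecting quantitative shifts would require cross-sample association
methods.

## Coordinates and geometry

All internal coordinates are 0-based half-open; BED output is 0-based,
VCF output 1-based. A boundary is stored as the junction coordinate
itself, equal to either the genomic start or end of the adjacent intron.
Scan windows are 3 exonic + 6 intronic bases (donor) and 6 intronic + 1
exonic base (acceptor), mirrored on the minus strand. Scoring windows are
larger on the acceptor side (20 intronic + 3 exonic bases, the classical
maximum-entropy acceptor geometry): variants are *scanned* in the 7-base
window but *scored* in the 23-base window. Windows sharing (chrom,
boundary, side, strand) across isoforms are merged, accumulating
transcript ids, so one physical splice site yields one call.

## Detection parameters

| parameter | default | meaning |
|---|---|---|
| min_var_reads | 3 | pileup supports per candidate |
| min_vaf | 0.05 | pileup allele fraction |
| min_mapq | 20 | MAPQ floor; secondary/supplementary/duplicate/unmapped excluded |
| min_positions | 3 | distinct variant offsets within supporting reads |
| edge_window / edge_rule | 5 / outside | see "edge clause" below |
| min_ir_pos | 3 | retention reads carrying the variant |
| min_specificity | 0.9 | #IR_Pos/(#IR_Pos+#IR_Neg) |
| min_penetrance | 0.1 | #IR_Pos/(#SJ_Neg+#IR_Pos) |
| min_intronic_cov | 25 bases | deepest intronic run of any IR_Pos read |
| delta_threshold | 2.5 bits | motif-score reduction, inclusive |
| max_af | 0.01 | population AF; strictly greater is removed |

All ratio thresholds are inclusive (≥). Multi-allelic sites are processed
one alternative at a time; indels are left-aligned to minimal
representation before AF lookup and merging. The library is treated as
unstranded: read orientation is ignored for counting. Base qualities are
not consulted; the position-diversity and specificity rules carry the
artifact-suppression burden instead.

**The edge clause.** The position-diversity filter demands ≥ 3 distinct
variant offsets within supporting reads plus an edge condition whose
published phrasing ("at least one of which must be inside the 5 bases from
the edges") admits two readings. The default here requires at least one
supporting read to carry the variant in the read *interior* (≥ 5 bases from
both edges) — the standard guard against boundary misalignment artifacts,
which cluster variant support at read edges; requiring an *edge* support
instead would discard roughly one in five genuine variants at 50× depth for
no specificity gain. The opposite reading remains available as
`edge_rule="inside"`.

## Read classification by realignment

Reads at the boundary are realigned against the reference and alternative
haplotype windows (±30 bp around the boundary) with a fit alignment (read
segment free to slide within the window; match +2, mismatch −4, gap open
−6, extend −1). A read is variant-positive iff its alternative-haplotype
score strictly exceeds the reference score; ties — e.g. a read ending
exactly at the variant — count as negative, protecting precision. A read is
a junction read when a CIGAR reference-skip edge coincides with the
boundary, and a retention read when one contiguous aligned run (deletions
merged, skips splitting) covers at least one base on each side. Reads doing
neither are ignored, so the four classes partition the counted reads.

## Splice-motif model

The motif scorer is an additive per-position log-odds table in bits:
`log2((count+pc)/(n+4·pc)) − log2(background)`, pseudocount 0.5, uniform
background by default, trained on the annotated splice sites of the genome
at hand (≥ 10 sites required). Geometry matches the published
maximum-entropy tables (donor 9-mer, acceptor 23-mer) and the scorer is
pluggable, so externally supplied score tables can be dropped in; the
additive model ignores inter-position dependence, which is acceptable here
because only the *reduction* between two nearly identical sequences is
thresholded. For indels the alternative window is rebuilt from the edited
haplotype re-anchored at the boundary: the junction keeps its place and
flanking bases shift.

## Quantification

A boundary's retention count is the number of reads aligned contiguously
over ≥ 10 bases on both sides; its spliced count is the number of reads
spliced at that junction covering the adjacent ("last") exonic base.
Quantification is variant-agnostic. Two ratios are reported: the plain
fraction ir/(ir+spliced) (missing when no reads qualify, never coerced to
zero) and the +1-smoothed local ratio e/(s+e+1) used for local retention
comparisons; the smoothing strictly shrinks the ratio and keeps it finite
at zero coverage.

## Consequence and NMD

For each call the harboring transcript with the greatest summed exon
length is chosen (ties broken by lexicographic transcript id). The
intron-retained mRNA is built by merging the flanking exons; translation
proceeds from the annotated start in the annotated frame, and a PTC is the
first in-frame stop strictly upstream of the original termination codon's
(mapped) position. The 50nt rule is evaluated on the *retained* transcript
— the retained intron's own junction no longer exists in the product NMD
surveys — with strict inequality: a PTC exactly 50 nt upstream of the last
junction is called insensitive. A CDS whose length is not a multiple of 3
is scanned in the annotated frame with a warning. The 50nt rule is a
deliberate simplification; physiological NMD efficiency is more complex
and is not modeled.

## Mutation status

DNA evidence is collected by the same realignment rule restricted to
contiguous reads. The flowchart defaults — min_depth 8 per side, min_var
3, germline when normal VAF ≥ 0.25, somatic requiring ≤ 1 variant read in
a well-covered normal — are conventional tumor/normal practice exposed as
configuration, since the published flowchart names its branches but not
its numeric cut-offs. The branch order (ambiguous on double
under-coverage, then false positive, germline, somatic,
somatic-or-germline, ambiguous) makes the five statuses a partition of the
evidence space.

## ClinVar tiers

Rules fire in order 1→4; first match wins, else tier 5. Tier 2 requires a
splice donor/acceptor molecular-consequence tag and a position inside the
call's scan window. Tier 3 measures the 30-bp distance along the chosen
transcript's mRNA (exonic path), so intronic truncating records cannot
match. Tier 4 requires the call to be NMD-sensitive and the same-gene
record to be *truncating* (nonsense/frameshift) with solid review status
(multiple submitters without conflicts, expert panel, or practice
guideline); the solid-review constraint applies to tier 4 only. The
review-status key is read from CLNREVSTAT with CLNSTAT accepted as an
alternate spelling. Drug-response flags apply the identical rules with
`CLNSIG=Drug_response` records as the reference set.

## Association statistics

The Z-value is (mean₊ − mean₋)/sd₋ — the carrier effect in units of the
non-carrier spread (sample sd, n−1), with a pooled-spread variant behind a
flag; constant backgrounds yield a signed infinity sentinel (0 when the
means agree). The permutation test permutes carrier labels preserving
group sizes with the carrier-group mean as statistic, switching
automatically to exhaustive enumeration when C(n,k) ≤ n_perm (p =
#{perm ≥ obs}/total) and using +1-smoothed Monte-Carlo otherwise so p > 0.
Wilcoxon rank-sum tests are one-sided (carriers greater), exact when the
smaller group has ≤ 10 samples and no ties, else normally approximated
with continuity and tie correction — mirroring R's `wilcox.test`.
Fisher's method combines per-group p-values as χ² = −2Σln p on 2k df;
zero p-values are rejected with guidance to floor them upstream. P-values
are reported raw; multiple-testing correction across variants is left to
the user (Benjamini–Hochberg downstream). All stochastic operations take a
single integer seed and record it in their output.

## The simulator

`ironspot.simulate` emulates the read configurations the detector keys on:
multi-exon genes on alternating strands (one per chromosome), canonical
splice motifs (donor CAG|GTAAGT, acceptor polypyrimidine+CAG|G, essential
dinucleotides fixed, other positions jittered at 10% so trained models are
informative), and reads sampled uniformly along the transcript. Each
planted variant is carried per-read at its RNA allele fraction; carrier
reads crossing the target junction retain the intron with probability
`ir_penetrance`, and variant-free plants model innate retention for
control-panel construction. DNA reads are contiguous, with germline plants
present in tumor and normal and somatic plants in tumor only, at the DNA
allele fraction (default 0.5, a heterozygote — the RNA fraction may differ
to emulate allelic expression imbalance). Reads are emitted as
already-aligned BAM records with exact M/N CIGARs, making truth files
exact; a FASTQ export exists for users who want a real aligner in the
loop. Defaults: 20 genes, 3–5 exons of 80–160 bp, introns 80–200 bp,
100-bp reads, 50× RNA / 60× DNA depth, 0.1% per-base error. Simulated
variants are substitutions; indel detection paths are exercised with
hand-built alignments in the test suite instead. What the simulator does
*not* model — fragment-length and expression-level variation, soft-clip
fuzz at junctions (available behind an option), alignment errors,
multi-mapping — bounds what passing tests show about real data: they
validate the decision logic and its thresholds, not robustness to aligner
artifacts.

Scene generation is deterministic given the seed (byte-identical outputs);
`read_seed` lets cohort studies vary reads over a fixed genome.

## Problem sizes

The shipped verification uses desk-scale scenes chosen to exercise every
rule while staying quick: recovery on 20 genes × 30 planted IRAVs at 50×
(recall ≥ 0.95, precision 1.0), specificity on 20 × 100-boundary null
scenes at 100× and 0.1% error (0 calls), read-classification and
translation oracles on ≤ 200-read loci over both strands, and statistical
closed forms with a 1000-replicate null-uniformity check. Archive-scale
counts from real cohorts require external data and are out of scope.

## Known limitations

- The motif scorer is a position-weight model, not the published
  maximum-entropy tables; absolute scores differ even though the filter
  semantics (reduction ≥ 2.5) match. Supplying true tables via the model
  file format recovers them exactly.
- Detection requires the retained intron to be absent from the control
  panel's innate-retention set; quantitative retention shifts are not
  detected by design.
- DNA status interrogates only already-called sites; it is not a somatic
  variant caller.
- NMD prediction is the 50nt rule only.
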