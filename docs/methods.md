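# Methods

## Scope and model

`nbscreen` models the automated stage of a genomic newborn-screening
pipeline: given caller output (small-variant VCFs, CNV calls), a panel of
gene–condition pairs, and curated knowledge resources, it emits the set of
calls a clinical scientist should review. Prioritization is intentionally
high-recall/rule-based rather than probabilistic: every decision is a
deterministic predicate over explicit, auditable thresholds, because a
screening programme must be able to explain — and tune — exactly why a
variant was or was not flagged. Alignment, variant calling and consequence
annotation are upstream concerns: the package consumes their outputs and
asserts their contracts (e.g. depth tracks are assumed to be computed with
MQ > 10, BQ > 30 and soft-clipped reads removed; this provenance is not
recomputed from alignments).

## Coordinates and normalization

All internal coordinates are 1-based inclusive (VCF convention). BED and
bedGraph inputs are converted once, on read. Multi-allelic records are
split before any rule runs, since all matching is per-allele. Alleles are
reduced to a minimal representation (shared prefix/suffix trimmed) and,
when a reference sequence is available, left-aligned with the standard
iterative trim-and-extend algorithm; at the contig boundary the allele is
re-anchored by extending to the right so the REF field remains a true
reference substring. Normalization is applied to *both* sides of every
coordinate match (variant calls and knowledge-base/exclusion entries), so
representation differences cannot cause missed or spurious matches.

Multi-nucleotide variants (equal-length substitutions of length > 1) are
decomposed positionwise into SNVs for frequency lookup; the minimum AF over
the components is used, because population references rarely carry the
joint allele and the joint event can be no more common than its rarest
component. Protein-change strings are canonicalized (strip `p.` and
parentheses, one-letter → three-letter, `*` → `Ter`) so string equality
defines protein matching.

## Knowledge sources and the conflicting-interpretation policy

Four source kinds carry distinct eligibility rules (see README). Two
choices deserve explanation:

* **What counts as a conflicting interpretation (CIP).** A variant is
  treated as CIP when its records span more than one of the categories
  {P/LP, VUS, B/LB}. Concordant variants are eligible only when all records
  are P/LP. The five CIP scenarios (`none`, `p_and_no_b`, `p_and_le1_b`
  — the default, `le1_b`, `all`) then form a strict containment chain:
  every scenario admits all variants the previous one admits. This is the
  weakest definition under which the chain property holds and the default
  scenario reduces to "≥ 1 P/LP and ≤ 1 B/LB".
* **Protein matching** is enabled for the archive-style sources only
  (disabled for the curated commercial source, whose classifications are
  coordinate-specific), never for MNVs, and is constrained to the same gene
  but not to a single transcript — transcript-level provenance of archive
  records is too unreliable to gate on.

Exclusion always wins: an excluded variant is removed before any source is
consulted, under every configuration. A helper emits candidate exclusion
entries for knowledge-base records falling inside a *different* panel
gene's padded span, since coordinate matching alone cannot distinguish
overlapping genes; these candidates are for curation, not automatic use.

## Mode-of-inheritance gating and phasing

MOI is a property of the gene–condition pair, not the variant. Monoallelic:
every individually qualifying genotype passes. Biallelic: homozygotes pass
alone; heterozygous candidates pass only in groups of ≥ 2 effective
alleles. Read-based phasing is trusted only within the configured window
(150 bp, the realistic span of read-backed phase sets): two heterozygotes
sharing a phase set and haplotype index within the window are merged into
one effective allele (in cis); a phased-trans pair within the window is
labelled `biallelic_comphet_trans`; everything else is
`biallelic_comphet_unphased` and deliberately kept — false-positive
compound hets are accepted as the price of not missing true ones, and the
co-occurrence classifier in the evaluation module quantifies that cost.

X-linked genes (the paper-level policy does not specify details; these are
this package's documented defaults, all configurable): hemizygous calls
pass alone, homozygous calls pass, a lone heterozygote does not; pLoF and
CNV frequency thresholds use the stricter monoallelic values. A prioritized
CNV loss may pair with a heterozygous small variant to satisfy a biallelic
gene (`cnv_comphet_with_snv`, default on); a CNV with copy number 0 counts
as homozygous. Complex-allele support is implemented as *companion flags*:
when a configured trigger variant is prioritized, the sample's genotype at
each companion position (including "absent") is attached to the call —
informing review without ever changing prioritization.

## Thresholds

| parameter | default | notes |
| --- | --- | --- |
| internal AF cap (reported variants) | 0.05 | fraction; MNVs use min decomposed AF |
| pLoF population AF cap | 1e-4 monoallelic / 5e-3 biallelic | per tier; policy values, surfaced in the run manifest |
| pLoF internal-AF mode | `population` | the same per-MOI caps also gate the internal AF (alternative: the 0.05 reported cap) |
| CNV loss AF cap | 0.001 / 0.005 (dominant/recessive) | against the CNV reference set |
| CNV gain AF cap | 0.002 / 0.01 | |
| CNV reciprocal overlap | 0.8 | reference-set matching |
| CNV flank | 2000 bp | padding for coding-region overlap |
| gene window | 50 bp | reported-variant proximity to the gene span (gene body, not transcript, by default) |
| phasing window | 150 bp | |
| coverage gate | median & mean < 30× and ≥ 95 % of bases < 15× | both must hold to exclude |
| callability cut-off | 0.5 | fraction of gene span in homology-excluded regions; applies to CNV-predominant genes only |
| Wilson z | 1.96 | conventional value, not the exact 1.959964 quantile |
| high-impact consequences | stop_gained, frameshift, splice acceptor/donor, start_lost, stop_lost, transcript_ablation | configurable set |

"95 % of the gene with coverage < 15×" is read as fraction-below-15× ≥ 0.95
over the exonic bases used for the metrics (exonic, not full genomic span,
by default); the inequality direction is forced by the poor-coverage
context. Transcript selection for pLoF prefers MANE Select > MANE Clinical
> predefined canonical, breaking ties by longest coding sequence then
lexicographic transcript id, so results are deterministic.

## Evaluation statistics

Specificity is **sample-level** — the fraction of samples with no
prioritized call — because review workload is counted in samples, not
variants. Confidence intervals are closed-form Wilson score intervals
(well behaved near proportion 1; the test suite cross-checks them against
an independent numerical inversion of the score test and against
statsmodels). Cohort comparisons use the pooled two-proportion z-test; both
the plain and the Yates-continuity-corrected variant are exposed because
published comparisons use either, and the two printed reference p-values
this package reproduces require one of each. Sensitivity supports masking
an evidence source, for validation designs where the diagnostic variants
themselves came from one of the sources. Co-occurrence classification of
compound-het pairs consumes a local symmetric lookup table (a stand-in for
a live population co-occurrence service); fractions are over queryable
pairs, with non-queryable pairs reported separately and an undefined
(None) result rather than 0.0 when nothing is queryable.

## The synthetic cohort

The generator fabricates a four-contig genome (~100 kb each) with eleven
invented gene models chosen so that every rule has a dedicated, isolated
exercise: dominant/recessive reported variants, protein-only matches, an
MNV, an AF-vetoed common variant, an excluded artefact, a pLoF in a
non-LoF gene, hom/single-het/cis/trans recessive configurations, three CIP
mixtures separating the five scenarios, an inclusion-list-only gene, a
complex-allele trigger/partner/excluded-component triple, X-linked hemi and
het, and rare/common CNV losses. Interacting categories live in separate
genes so each sample's truth is independent of which other categories it
carries. Carrier rates default to 3–10 % per category — far above any real
population, deliberately, so a 200-sample cohort exercises every rule;
consequently the synthetic cohort's specificity (~66 %) is a property of
the fixture design, not an estimate of screening performance. Each
category draws carriers from its own seeded substream, so changing one rate
leaves all other carrier sets untouched, and a fixed seed makes every
output file byte-identical.

What passing the truth table shows: the engine implements the stated rules
exactly on inputs whose annotations and knowledge records are consistent by
construction. What it does not show: robustness to annotation
disagreement, caller artefacts, or population structure — none of which the
generator models.

## Problem sizes

The test suite and acceptance script run at deliberately modest sizes — a
200-sample cohort for end-to-end recovery, 1,000 random instances per
numeric oracle, 200–300 cases for normalization and AF oracles — chosen so
the whole validation completes in seconds while every rule path and
boundary case is covered.

## Known limitations

* CNV calls carry no genotype likelihoods; dosage is inferred from copy
  number (0 → homozygous) and otherwise treated as one allele.
* The engine assumes one annotation dialect (sidecar TSV or the package's
  own VCF writer); arbitrary VEP/CSQ strings are not parsed.
* X-chromosome handling is genotype-driven; no sex-aware coverage or
  pseudo-autosomal logic (coverage QC on X should use female samples).
* Structural variation beyond loss/gain CNVs (insertions, inversions,
  repeat expansions) is out of scope.
* The reportability of a prioritized variant is a manual decision; the
  evaluation module only models it as an input label.
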