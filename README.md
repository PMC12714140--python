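# nbscreen

Automated variant prioritization for genomic newborn screening, with the
gene-level QC gating and the specificity/sensitivity framework needed to
validate it before genes enter a screening panel.

## The problem

Population-scale newborn screening by genome sequencing must review
candidate variants in hundreds of gene–condition pairs while keeping
false-positive results — and clinical-scientist workload — to a minimum.
`nbscreen` implements the automated *prioritization* step of such a
pipeline: a deterministic rule engine that decides which small variants and
copy-number variants (CNVs) in a panel are flagged for manual review. It
does **not** classify variants or decide reportability; those remain manual
steps downstream.

## The rules

A variant is prioritized when all of the following hold:

1. **Universal filters** — caller `PASS` status; chromosome 1–22/X; not on
   the curated exclusion list (sequencing artefacts, low-penetrance alleles,
   out-of-scope conditions, complex-allele components). Exclusion wins over
   every other rule.
2. **At least one evidence route fires:**
   * *Previously reported pathogenic* — within 50 bp of a panel gene, internal
     cohort allele frequency AF < 0.05 (for multi-nucleotide variants, the
     minimum AF over the decomposed SNVs), and a qualifying record in a
     knowledge base. Source-specific rules: a ClinVar-like archive requires
     ≥ 1 P/LP and ≤ 1 B/LB classification (configurable across five
     conflicting-interpretation scenarios) and supports matching by
     identical predicted protein change (never for MNVs); a clinical-archive
     source requires ≥ 1 P/LP with protein matching; a curated commercial
     source requires a P/LP classification by exact coordinates only;
     internal inclusion lists match exactly and must cite PubMed evidence —
     for designated genes they are the *only* admissible source.
   * *Predicted loss of function (pLoF)* — high-impact consequence on the
     MANE Select / MANE Clinical / predefined reference transcript, in a
     gene where LoF is the mechanism of disease, rare in every population
     tier (monoallelic < 1 × 10⁻⁴, biallelic < 5 × 10⁻³ by default).
   * *CNV loss of function* — the event ± 2 kb overlaps the gene's coding
     region; gains must have both breakpoints inside the transcript;
     reference-set frequency at 80 % reciprocal overlap below the
     type-and-inheritance threshold (losses: < 0.001 dominant / < 0.005
     recessive; gains: < 0.002 / < 0.01). Mid-size (2–10 kb) CNVs are only
     `PASS` when an independent SV caller confirms them at ≥ 50 % reciprocal
     overlap.
   * *SMN1* — the case is prioritized when the targeted caller infers zero
     intact copies of *SMN1*.
3. **Mode-of-inheritance gate** — monoallelic conditions accept any
   qualifying genotype; biallelic conditions require homozygosity or two or
   more heterozygous candidates forming a *potential compound heterozygote*.
   Read-based phasing (trusted within ~150 bp) collapses pairs proven in
   cis; unphased pairs are kept for manual review. A lone heterozygote in a
   recessive-only gene is never prioritized.

The validation framework computes **sample-level specificity**
`100 × (1 − flagged/n)` with Wilson score intervals, pooled two-proportion
z-tests (with or without continuity correction), sensitivity over cohorts
with known diagnostic variants, and haplotype co-occurrence classification
of compound-het pairs. Gene QC excludes a gene only when poor coverage
affects essentially the whole gene (median and mean < 30×, ≥ 95 % of bases
< 15×) or CNV callability is compromised in a CNV-predominant gene.

## Worked example

Generate a 50-sample synthetic cohort with planted variants of known
outcome, run the engine, and evaluate:

```bash
nbscreen simulate --seed 42 --n-samples 50 --out demo
nbscreen prioritize \
  --panel demo/panel.tsv --knowledge demo/knowledge.tsv \
  --exclusion demo/exclusion.tsv --internal-af demo/internal_af.tsv \
  --population-af demo/population_af.tsv --cnv-reference demo/cnv_reference.tsv \
  --annotations demo/annotations.tsv --companions demo/companions.tsv \
  --vcf-dir demo/vcf --cnvs demo/cnvs.tsv --out demo/report.tsv
nbscreen evaluate --report demo/report.tsv --n-samples 50 --out demo/eval.tsv
```

`prioritize` logs `samples: 50  flagged: 19` and writes one row per
prioritized call with full rule provenance:

```
sample       contig  pos    ref  alt  gene   sources       zygosity_rationale
sample_0000  2       55000  A    T    CIP1   clinvar_like  monoallelic_het
sample_0001  3       15000  G    A    CPLX1  clinvar_like  biallelic_comphet_unphased
sample_0001  3       16000  C    T    CPLX1  clinvar_like  biallelic_comphet_unphased
```

`sample_0000` carries a variant with conflicting interpretations (1 P, 1 B)
that qualifies under the default scenario; `sample_0001` carries two
unphased heterozygotes in a recessive gene, kept jointly as a potential
compound heterozygote. `evaluate` summarizes per source with Wilson CIs:

```
source        unique_variants  flagged_samples  specificity_pct  ci_low_pct  ci_high_pct
clinvar_like  6                10               80.0             66.96       88.76
...
all           13               19               62.0             48.15       74.14
```

(The low specificity is by construction — this tiny demo cohort plants
carriers at far higher rates than a real screening population.)

Every command writes a `*.manifest.json` capturing the full threshold
configuration and SHA-256 digests of its inputs, so any output can be
reproduced from its manifest.

## Layout

| module | role |
| --- | --- |
| `nbscreen.datamodel` | variant/CNV model, normalization, MNV decomposition, VCF/TSV I/O |
| `nbscreen.knowledge` | panel, knowledge bases, exclusion list, frequency references, thresholds |
| `nbscreen.engine` | the prioritization rule engine |
| `nbscreen.gene_qc` | coverage and CNV-callability gating |
| `nbscreen.evaluation` | specificity/sensitivity statistics and scenario sweeps |
| `nbscreen.synthetic` | deterministic fixture-cohort generator with truth tables |
| `nbscreen.cli` | `nbscreen prioritize | evaluate | gene-qc | simulate` |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and known limitations.
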