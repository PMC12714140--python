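"""Deterministic synthetic-cohort generator for pipeline validation.

Emulates the two validation cohorts the pipeline is assessed on — a large
cohort not enriched for rare disease (specificity) and a cohort of samples
carrying known diagnostic variants (sensitivity) — on a fabricated genome
of short contigs with invented gene models. Every planted-variant category
exercises one rule of the engine and carries a ground-truth expectation, so
an end-to-end run can be scored against the truth table exactly.

The generator does not attempt read-level realism or population-genetic
structure: variants are planted at configured carrier rates with exact
knowledge-base/frequency records, which is what the rule engine consumes.

A single master seed drives everything; each category draws its carriers
from its own spawned substream, so changing one category's rate leaves the
other categories' carrier sets untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CnvCall,
    GenotypeCall,
    NormalizedVariant,
    cnv_calls_from_frame,
    read_annotation_table,
    read_cnv_tsv,
    read_small_variant_vcf,
    write_small_variant_vcf,
)
from .engine import SampleData
from .knowledge import (
    load_companions,
    load_exclusion,
    load_frequencies,
    load_knowledge,
    load_panel,
)

CONTIG_LENGTHS = {"1": 100_000, "2": 100_000, "3": 100_000, "X": 100_000}

#: panel rows: gene, condition, moi, lof, inclusion_only, contig, start, end,
#: transcript, coding_exons
_PANEL_ROWS = [
    ("DOM1", "cond_dom1", "monoallelic", False, False, "1", 10_000, 20_000, "T_DOM1", ""),
    ("REC1", "cond_rec1", "biallelic", False, False, "1", 30_000, 40_000, "T_REC1", ""),
    ("REC2", "cond_rec2", "biallelic", False, False, "1", 50_000, 60_000, "T_REC2", ""),
    ("REC3", "cond_rec3", "biallelic", False, False, "1", 70_000, 80_000, "T_REC3", ""),
    ("REC4", "cond_rec4", "biallelic", False, False, "2", 10_000, 20_000, "T_REC4", ""),
    ("LOFD1", "cond_lofd1", "monoallelic", True, False, "2", 30_000, 40_000, "T_LOFD1", ""),
    ("CIP1", "cond_cip1", "monoallelic", False, False, "2", 50_000, 60_000, "T_CIP1", ""),
    ("INCL1", "cond_incl1", "monoallelic", False, True, "2", 70_000, 80_000, "T_INCL1", ""),
    ("CPLX1", "cond_cplx1", "biallelic", False, False, "3", 10_000, 20_000, "T_CPLX1", ""),
    ("CNV1", "cond_cnv1", "monoallelic", True, False, "3", 30_000, 60_000, "T_CNV1",
     "32000-34000;40000-42000;55000-57000"),
    ("XL1", "cond_xl1", "x_linked", False, False, "X", 10_000, 20_000, "T_XL1", ""),
]


@dataclass(frozen=True)
class _Plant:
    """A small variant planted by one category."""

    contig: str
    pos: int
    ref: str
    alt: str
    gene: str
    zygosity: str = "het"
    phase_set: int | None = None
    haplotype: int | None = None
    consequence: str = "missense_variant"
    impact: str = "moderate"
    protein_change: str | None = None
    expect: bool = True


@dataclass(frozen=True)
class _CnvPlant:
    contig: str
    start: int
    end: int
    cnv_type: str
    gene: str
    filter_status: str = "PASS"
    expect: bool = True


@dataclass(frozen=True)
class _Category:
    name: str
    rate: float
    small: tuple = ()
    cnvs: tuple = ()


_CATEGORIES = (
    _Category("dom_reported", 0.05, small=(
        _Plant("1", 15_000, "A", "G", "DOM1", protein_change="Arg100Gly", expect=True),)),
    _Category("protein_match", 0.03, small=(
        _Plant("1", 13_000, "A", "T", "DOM1", protein_change="Arg50Ter", expect=True),)),
    _Category("mnv_reported", 0.03, small=(
        _Plant("1", 14_000, "AG", "TC", "DOM1", expect=True),)),
    _Category("common_reported", 0.05, small=(
        _Plant("1", 17_000, "T", "C", "DOM1", expect=False),)),
    _Category("artefact_excluded", 0.05, small=(
        _Plant("1", 18_000, "G", "C", "DOM1", expect=False),)),
    _Category("plof_nonlof", 0.03, small=(
        _Plant("1", 16_000, "C", "A", "DOM1", consequence="stop_gained",
               impact="high", expect=False),)),
    _Category("rec_single_het", 0.05, small=(
        _Plant("1", 35_000, "C", "T", "REC1", expect=False),)),
    _Category("rec_hom", 0.03, small=(
        _Plant("1", 55_000, "G", "A", "REC2", zygosity="hom_alt", expect=True),)),
    _Category("comphet_trans", 0.04, small=(
        _Plant("1", 75_000, "C", "T", "REC3", expect=True),
        _Plant("1", 78_500, "A", "G", "REC3", expect=True))),
    _Category("comphet_cis", 0.04, small=(
        _Plant("2", 15_000, "C", "A", "REC4", phase_set=15_000, haplotype=1,
               expect=False),
        _Plant("2", 15_100, "G", "T", "REC4", phase_set=15_000, haplotype=1,
               expect=False))),
    _Category("plof_dom", 0.04, small=(
        _Plant("2", 35_000, "G", "T", "LOFD1", consequence="stop_gained",
               impact="high", expect=True),)),
    _Category("cip_eligible", 0.04, small=(
        _Plant("2", 55_000, "A", "T", "CIP1", expect=True),)),
    _Category("cip_ineligible", 0.04, small=(
        _Plant("2", 56_000, "C", "G", "CIP1", expect=False),)),
    _Category("cip_le1b_only", 0.03, small=(
        _Plant("2", 57_000, "T", "A", "CIP1", expect=False),)),
    _Category("inclusion_hit", 0.03, small=(
        _Plant("2", 75_000, "G", "A", "INCL1", expect=True),)),
    _Category("incl_only_blocked", 0.03, small=(
        _Plant("2", 76_000, "C", "T", "INCL1", expect=False),)),
    _Category("complex_pair", 0.03, small=(
        _Plant("3", 15_000, "G", "A", "CPLX1", expect=True),
        _Plant("3", 16_000, "C", "T", "CPLX1", expect=True),
        _Plant("3", 17_000, "G", "C", "CPLX1", expect=False))),
    _Category("xl_hemi", 0.03, small=(
        _Plant("X", 15_000, "C", "T", "XL1", zygosity="hemi", expect=True),)),
    _Category("xl_single_het", 0.03, small=(
        _Plant("X", 16_000, "G", "A", "XL1", expect=False),)),
    _Category("cnv_loss", 0.03, cnvs=(
        _CnvPlant("3", 33_000, 48_999, "loss", "CNV1", expect=True),)),
    _Category("cnv_common", 0.03, cnvs=(
        _CnvPlant("3", 40_000, 55_999, "loss", "CNV1", expect=False),)),
    _Category("background_benign", 0.10, small=(
        _Plant("1", 19_000, "T", "A", "DOM1", expect=False),)),
)

DEFAULT_RATES = {c.name: c.rate for c in _CATEGORIES}


@dataclass
class SimulationSpec:
    """Configuration of one synthetic cohort.

    ``rates`` maps category name -> carrier fraction; unspecified
    categories keep their defaults. A fixed seed makes every output file
    byte-identical between runs.
    """

    seed: int = 0
    n_samples: int = 200
    rates: dict = field(default_factory=dict)
    depth_mean: float = 35.0
    depth_sd: float = 6.0

    def __post_init__(self) -> None:
        unknown = set(self.rates) - set(DEFAULT_RATES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        for name, rate in self.rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"rate for {name} must be in [0,1]")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")

    def rate(self, name: str) -> float:
        return self.rates.get(name, DEFAULT_RATES[name])


def _sample_ids(n: int) -> list[str]:
    return [f"sample_{i:04d}" for i in range(n)]


def _carriers(spec: SimulationSpec, category_index: int, name: str) -> np.ndarray:
    """Deterministic carrier subset for one category via its own substream."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, category_index]))
    k = int(round(spec.rate(name) * spec.n_samples))
    if k == 0:
        return np.array([], dtype=int)
    return np.sort(rng.choice(spec.n_samples, size=k, replace=False))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Write per-sample VCFs, the CNV call table, and the truth table.

    The truth table lists, per sample, every planted variant together with
    whether it should be prioritized under the default configuration.
    """
    outdir = Path(outdir)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    samples = _sample_ids(spec.n_samples)

    plants_by_sample: dict[str, list[_Plant]] = {s: [] for s in samples}
    cnvs_by_sample: dict[str, list[_CnvPlant]] = {s: [] for s in samples}
    truth_rows = []
    for index, cat in enumerate(_CATEGORIES):
        for si in _carriers(spec, index, cat.name):
            sample = samples[si]
            for plant in cat.small:
                plants_by_sample[sample].append(plant)
                truth_rows.append({
                    "sample": sample, "category": cat.name, "kind": "small",
                    "contig": plant.contig, "pos": plant.pos,
                    "ref": plant.ref, "alt": plant.alt,
                    "start": "", "end": "", "cnv_type": "",
                    "gene": plant.gene, "expect_prioritized": plant.expect,
                })
            for cnv in cat.cnvs:
                cnvs_by_sample[sample].append(cnv)
                truth_rows.append({
                    "sample": sample, "category": cat.name, "kind": "cnv",
                    "contig": cnv.contig, "pos": "", "ref": "", "alt": "",
                    "start": cnv.start, "end": cnv.end, "cnv_type": cnv.cnv_type,
                    "gene": cnv.gene, "expect_prioritized": cnv.expect,
                })

    for sample in samples:
        records = []
        for plant in sorted(
            plants_by_sample[sample], key=lambda p: (p.contig, p.pos, p.alt)
        ):
            v = NormalizedVariant(
                contig=plant.contig, pos=plant.pos, ref=plant.ref, alt=plant.alt
            )
            call = GenotypeCall(
                sample_id=sample,
                variant_key=v.key,
                zygosity=plant.zygosity,
                phase_set_id=(
                    f"{plant.contig}:{plant.phase_set}"
                    if plant.phase_set is not None else None
                ),
                haplotype_index=plant.haplotype,
            )
            records.append((v, {sample: call}))
        write_small_variant_vcf(
            vcf_dir / f"{sample}.vcf", records, [sample], CONTIG_LENGTHS
        )

    cnv_rows = [
        {"sample": sample, "contig": c.contig, "start": c.start, "end": c.end,
         "type": c.cnv_type, "filter": c.filter_status, "copy_number": ""}
        for sample in samples for c in cnvs_by_sample[sample]
    ]
    cnv_path = outdir / "cnvs.tsv"
    pd.DataFrame(
        cnv_rows,
        columns=["sample", "contig", "start", "end", "type", "filter", "copy_number"],
    ).to_csv(cnv_path, sep="\t", index=False)

    truth_path = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return {"vcf_dir": vcf_dir, "cnvs": cnv_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# knowledge-base / reference generation
# ---------------------------------------------------------------------------

def _kb_rows() -> list[dict]:
    def row(source, contig, pos, ref, alt, gene, classification,
            protein="", evidence=""):
        return {
            "source": source, "contig": contig, "pos": pos, "ref": ref,
            "alt": alt, "gene": gene, "protein_change": protein,
            "classification": classification, "evidence_ids": evidence,
        }

    rows = [
        # concordant pathogenic, coordinate-keyed
        row("clinvar_like", "1", 15_000, "A", "G", "DOM1", "P"),
        row("clinvar_like", "1", 15_000, "A", "G", "DOM1", "P"),
        # protein-keyed only: reachable through protein matching
        row("clinvar_like", "", "", "", "", "DOM1", "P", protein="Arg50Ter"),
        # MNV known to the curated commercial source by coordinates
        row("curated_commercial", "1", 14_000, "AG", "TC", "DOM1", "P"),
        # common variant: pathogenic record but internal AF will veto it
        row("clinvar_like", "1", 17_000, "T", "C", "DOM1", "P"),
        # recurrent artefact (also on the exclusion list)
        row("clinvar_like", "1", 18_000, "G", "C", "DOM1", "P"),
        row("clinvar_like", "1", 35_000, "C", "T", "REC1", "P"),
        row("curated_commercial", "1", 55_000, "G", "A", "REC2", "P"),
        row("cva_like", "1", 75_000, "C", "T", "REC3", "P"),
        row("cva_like", "1", 78_500, "A", "G", "REC3", "P"),
        row("clinvar_like", "2", 15_000, "C", "A", "REC4", "P"),
        row("clinvar_like", "2", 15_100, "G", "T", "REC4", "P"),
        # conflicting-interpretation mixtures
        row("clinvar_like", "2", 55_000, "A", "T", "CIP1", "P"),
        row("clinvar_like", "2", 55_000, "A", "T", "CIP1", "B"),
        row("clinvar_like", "2", 56_000, "C", "G", "CIP1", "P"),
        row("clinvar_like", "2", 56_000, "C", "G", "CIP1", "B"),
        row("clinvar_like", "2", 56_000, "C", "G", "CIP1", "B"),
        row("clinvar_like", "2", 57_000, "T", "A", "CIP1", "VUS"),
        row("clinvar_like", "2", 57_000, "T", "A", "CIP1", "B"),
        # inclusion-list-only gene
        row("internal_inclusion", "2", 75_000, "G", "A", "INCL1", "P",
            evidence="PMID:1000001,PMID:1000002"),
        row("clinvar_like", "2", 76_000, "C", "T", "INCL1", "P"),
        # complex-allele pair
        row("clinvar_like", "3", 15_000, "G", "A", "CPLX1", "P"),
        row("clinvar_like", "3", 16_000, "C", "T", "CPLX1", "P"),
        row("clinvar_like", "X", 15_000, "C", "T", "XL1", "P"),
        row("clinvar_like", "X", 16_000, "G", "A", "XL1", "P"),
        # concordant benign background
        row("clinvar_like", "1", 19_000, "T", "A", "DOM1", "B"),
    ]
    return rows


def generate_knowledge(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the panel, knowledge base, exclusion list, frequency
    references, annotation sidecar, companion table, and a co-occurrence
    table consistent with the planted cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    panel_df = pd.DataFrame(
        _PANEL_ROWS,
        columns=["gene", "condition", "moi", "lof_mechanism", "inclusion_list_only",
                 "contig", "start", "end", "transcript", "coding_exons"],
    )
    paths["panel"] = outdir / "panel.tsv"
    panel_df.to_csv(paths["panel"], sep="\t", index=False)

    paths["knowledge"] = outdir / "knowledge.tsv"
    pd.DataFrame(_kb_rows()).to_csv(paths["knowledge"], sep="\t", index=False)

    exclusion = pd.DataFrame(
        [
            {"contig": "1", "pos": 18_000, "ref": "G", "alt": "C",
             "reason": "artefact"},
            {"contig": "3", "pos": 17_000, "ref": "G", "alt": "C",
             "reason": "complex_allele_component"},
        ]
    )
    paths["exclusion"] = outdir / "exclusion.tsv"
    exclusion.to_csv(paths["exclusion"], sep="\t", index=False)

    internal = pd.DataFrame(
        [
            {"contig": "1", "pos": 15_000, "ref": "A", "alt": "G", "af": 0.002},
            {"contig": "1", "pos": 17_000, "ref": "T", "alt": "C", "af": 0.08},
            # decomposed components of the planted MNV: min(0.2, 0.01) passes
            {"contig": "1", "pos": 14_000, "ref": "A", "alt": "T", "af": 0.2},
            {"contig": "1", "pos": 14_001, "ref": "G", "alt": "C", "af": 0.01},
        ]
    )
    paths["internal_af"] = outdir / "internal_af.tsv"
    internal.to_csv(paths["internal_af"], sep="\t", index=False)

    population = pd.DataFrame(
        [
            {"contig": "2", "pos": 35_000, "ref": "G", "alt": "T",
             "tier": "global", "af": 0.00005},
        ]
    )
    paths["population_af"] = outdir / "population_af.tsv"
    population.to_csv(paths["population_af"], sep="\t", index=False)

    cnv_ref = pd.DataFrame(
        [
            {"contig": "3", "start": 40_000, "end": 55_999, "type": "loss",
             "frequency": 0.05},
            {"contig": "3", "start": 90_000, "end": 99_000, "type": "gain",
             "frequency": 0.2},
        ]
    )
    paths["cnv_reference"] = outdir / "cnv_reference.tsv"
    cnv_ref.to_csv(paths["cnv_reference"], sep="\t", index=False)

    companions = pd.DataFrame(
        [
            {"contig": "3", "pos": 15_000, "ref": "G", "alt": "A",
             "contig2": "3", "pos2": 17_000, "ref2": "G", "alt2": "C"},
        ]
    )
    paths["companions"] = outdir / "companions.tsv"
    companions.to_csv(paths["companions"], sep="\t", index=False)

    ann_rows = []
    for cat in _CATEGORIES:
        for p in cat.small:
            transcript = next(r[8] for r in _PANEL_ROWS if r[0] == p.gene)
            ann_rows.append({
                "contig": p.contig, "pos": p.pos, "ref": p.ref, "alt": p.alt,
                "gene": p.gene, "transcript": transcript,
                "consequence": p.consequence, "impact": p.impact,
                "protein_change": p.protein_change or "",
                "flags": "mane_select", "cds_length": "",
            })
    paths["annotations"] = outdir / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(paths["annotations"], sep="\t", index=False)

    cooccurrence = pd.DataFrame(
        [
            {"contig_a": "1", "pos_a": 75_000, "ref_a": "C", "alt_a": "T",
             "contig_b": "1", "pos_b": 78_500, "ref_b": "A", "alt_b": "G",
             "prediction": "different_haplotypes"},
            {"contig_a": "3", "pos_a": 15_000, "ref_a": "G", "alt_a": "A",
             "contig_b": "3", "pos_b": 16_000, "ref_b": "C", "alt_b": "T",
             "prediction": "uncertain"},
        ]
    )
    paths["cooccurrence"] = outdir / "cooccurrence.tsv"
    cooccurrence.to_csv(paths["cooccurrence"], sep="\t", index=False)

    return paths


def generate_bundle(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Full fixture bundle: cohort plus knowledge/reference files."""
    outdir = Path(outdir)
    paths = generate_knowledge(spec, outdir)
    paths.update(generate_cohort(spec, outdir))
    return paths


# ---------------------------------------------------------------------------
# depth-track generation for gene QC
# ---------------------------------------------------------------------------

def generate_depth_track(
    spec: SimulationSpec,
    contig: str,
    intervals,
    mean: float | None = None,
    stream: int = 10_000,
) -> pd.DataFrame:
    """Synthetic per-base depth over intervals as a 1-based bedGraph-style
    frame (integer depths, normally distributed, truncated at 0)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))
    mu = spec.depth_mean if mean is None else mean
    rows = []
    for lo, hi in intervals:
        depths = np.maximum(
            0, np.rint(rng.normal(mu, spec.depth_sd, hi - lo + 1))
        ).astype(int)
        for offset, d in enumerate(depths):
            rows.append({"contig": contig, "start": lo + offset,
                         "end": lo + offset, "depth": int(d)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loading a generated bundle back into engine inputs
# ---------------------------------------------------------------------------

def load_bundle(outdir: str | Path):
    """Read a generated fixture bundle into engine-ready objects.

    Returns (samples, panel, kb, exclusion, freqs, companions, truth).
    """
    outdir = Path(outdir)
    panel = load_panel(outdir / "panel.tsv")
    kb = load_knowledge(outdir / "knowledge.tsv")
    exclusion = load_exclusion(outdir / "exclusion.tsv")
    freqs = load_frequencies(
        outdir / "internal_af.tsv",
        outdir / "population_af.tsv",
        outdir / "cnv_reference.tsv",
    )
    companions = load_companions(outdir / "companions.tsv")
    annotations = read_annotation_table(outdir / "annotations.tsv")
    cnvs_by_sample = cnv_calls_from_frame(read_cnv_tsv(outdir / "cnvs.tsv"))
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t", keep_default_na=False)

    samples = []
    for vcf_path in sorted((outdir / "vcf").glob("*.vcf")):
        sample_id = vcf_path.stem
        small = list(read_small_variant_vcf(vcf_path, annotations))
        samples.append(
            SampleData(
                sample_id=sample_id,
                small_variants=small,
                cnvs=cnvs_by_sample.get(sample_id, []),
            )
        )
    return samples, panel, kb, exclusion, freqs, companions, truth
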