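"""The variant prioritization rule engine.

Prioritization selects candidate variants for manual clinical-scientist
review; it is not classification. A variant is prioritized when it passes
the universal filters (caller PASS status, supported contig, not on the
exclusion list), qualifies through at least one evidence route (previously
reported pathogenic, predicted loss of function, CNV loss-of-function, or
the SMN1 copy-number rule), and its genotype is compatible with the
condition's mode of inheritance. For biallelic conditions two heterozygous
candidates are kept as a potential compound heterozygote unless read-based
phasing places them in cis; a lone heterozygote is dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import (
    CnvCall,
    GenotypeCall,
    NormalizedVariant,
    TranscriptAnnotation,
    intervals_intersect,
    reciprocal_overlap,
)
from .knowledge import (
    ExclusionList,
    FrequencyReference,
    GeneConditionPair,
    KnowledgeBase,
    Thresholds,
    aggregate_classifications,
    is_excluded,
    match_variant,
    within_gene_window,
)

logger = logging.getLogger("nbscreen")

ALL_SOURCES = (
    "clinvar_like", "cva_like", "curated_commercial", "internal_inclusion",
    "plof", "cnv_plof", "smn1",
)

TRANSCRIPT_PREFERENCE = ("mane_select", "mane_clinical", "predefined_canonical")


@dataclass(frozen=True)
class SmnResult:
    """Targeted-caller output: inferred copies of intact SMN1."""

    sample_id: str
    intact_smn1_copy_number: int

    def __post_init__(self) -> None:
        if self.intact_smn1_copy_number < 0:
            raise ValueError("SMN1 copy number cannot be negative")


@dataclass
class PrioritizedCall:
    """One prioritization outcome for one sample, with rule provenance."""

    sample_id: str
    payload: object  # NormalizedVariant | CnvCall | SmnResult
    gene_condition: GeneConditionPair | None
    sources: frozenset
    zygosity_rationale: str
    companion_flags: list = field(default_factory=list)
    comphet_partners: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("a prioritized call must cite at least one source")

    @property
    def payload_key(self) -> tuple:
        return self.payload.key if hasattr(self.payload, "key") else ("smn1",)

    def sort_key(self) -> tuple:
        if isinstance(self.payload, NormalizedVariant):
            return (self.payload.contig, self.payload.pos, self.payload.ref,
                    self.payload.alt, "")
        if isinstance(self.payload, CnvCall):
            return (self.payload.contig, self.payload.start, "", "",
                    self.payload.cnv_type)
        return ("~smn1", 0, "", "", "")


@dataclass
class SampleData:
    """All caller output for one sample that the engine consumes."""

    sample_id: str
    small_variants: list = field(default_factory=list)  # [(NormalizedVariant, GenotypeCall)]
    cnvs: list = field(default_factory=list)  # [CnvCall]
    smn: SmnResult | None = None


@dataclass
class _Candidate:
    payload: object
    zygosity: str
    phase_set_id: str | None
    haplotype_index: int | None
    sources: set
    position: int

    @property
    def key(self) -> tuple:
        return self.payload.key


# ---------------------------------------------------------------------------
# universal filters
# ---------------------------------------------------------------------------

def universal_filter(
    item: NormalizedVariant | CnvCall, exclusion: ExclusionList
) -> tuple[bool, str | None]:
    """Gate applied to every call before any source rule.

    Fails on non-PASS filter status or exclusion-list membership (small
    variants only; CNVs are not coordinate-exact matchable). MOI
    compatibility is checked later by :func:`moi_gate`.
    """
    if not item.is_pass:
        return False, "filter_status"
    if isinstance(item, NormalizedVariant):
        excluded, _reason = is_excluded(item.key, exclusion)
        if excluded:
            return False, "excluded"
    return True, None


# ---------------------------------------------------------------------------
# mode-of-inheritance gating and compound-het phasing
# ---------------------------------------------------------------------------

def moi_gate(
    candidates: Sequence[_Candidate],
    moi: str,
    phasing_window_bp: int = 150,
) -> list[tuple[tuple, str]]:
    """Apply the mode-of-inheritance rules to a gene's candidate set.

    Returns (candidate-group, zygosity_rationale) pairs. Monoallelic:
    every candidate passes alone. Biallelic (and X-linked): hom-alt and
    hemizygous candidates pass alone; two or more heterozygous candidates
    pass jointly as a potential compound heterozygote unless read-based
    phasing places them on the same haplotype — two hets sharing a phase
    set and haplotype index within ``phasing_window_bp`` are in cis and
    collapse to a single allele. A lone het does not pass.
    """
    results: list[tuple[tuple, str]] = []
    if moi == "monoallelic":
        for c in candidates:
            if c.zygosity == "hom_alt":
                rationale = "monoallelic_hom"
            elif c.zygosity == "hemi":
                rationale = "hemizygous"
            else:
                rationale = "monoallelic_het"
            results.append(((c,), rationale))
        return results

    # biallelic and x_linked
    hets: list[_Candidate] = []
    for c in candidates:
        if c.zygosity == "hom_alt":
            results.append(((c,), "biallelic_hom"))
        elif c.zygosity == "hemi":
            results.append(((c,), "hemizygous"))
        else:
            hets.append(c)
    if len(hets) >= 2:
        groups = _collapse_cis(hets, phasing_window_bp)
        if len(groups) >= 2:
            rationale = "biallelic_comphet_unphased"
            if _any_trans_phased(hets, phasing_window_bp):
                rationale = "biallelic_comphet_trans"
            results.append((tuple(hets), rationale))
    return results


def _in_cis(a: _Candidate, b: _Candidate, window: int) -> bool:
    return (
        a.phase_set_id is not None
        and a.phase_set_id == b.phase_set_id
        and a.haplotype_index is not None
        and b.haplotype_index is not None
        and a.haplotype_index == b.haplotype_index
        and abs(a.position - b.position) <= window
    )


def _any_trans_phased(hets: Sequence[_Candidate], window: int) -> bool:
    for i, a in enumerate(hets):
        for b in hets[i + 1:]:
            if (
                a.phase_set_id is not None
                and a.phase_set_id == b.phase_set_id
                and a.haplotype_index is not None
                and b.haplotype_index is not None
                and a.haplotype_index != b.haplotype_index
                and abs(a.position - b.position) <= window
            ):
                return True
    return False


def _collapse_cis(hets: Sequence[_Candidate], window: int) -> list[list[_Candidate]]:
    """Union-find over in-cis relations; each group is one effective allele."""
    parent = list(range(len(hets)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(hets)):
        for j in range(i + 1, len(hets)):
            if _in_cis(hets[i], hets[j], window):
                parent[find(i)] = find(j)
    groups: dict[int, list[_Candidate]] = {}
    for i, c in enumerate(hets):
        groups.setdefault(find(i), []).append(c)
    return list(groups.values())


# ---------------------------------------------------------------------------
# per-source rules for previously reported variants
# ---------------------------------------------------------------------------

def prioritize_reported(
    variant: NormalizedVariant,
    pair: GeneConditionPair,
    kb: KnowledgeBase,
    freqs: FrequencyReference,
    thresholds: Thresholds,
) -> set[str]:
    """Evidence sources through which a previously reported variant
    qualifies for this gene-condition pair.

    Every source requires internal cohort AF < 0.05 (MNVs: minimum over
    decomposed SNVs; an absent frequency counts as rare). Inclusion-
    list-only genes accept only internal-inclusion records.
    """
    af = freqs.internal_for(variant)
    if af is not None and af >= thresholds.internal_af_max:
        return set()

    sources: set[str] = set()
    gene = pair.gene_symbol

    # internal inclusion list: exact match, PubMed-evidenced P/LP
    incl = [
        r for r in kb.exact("internal_inclusion", variant.key)
        if (r.gene is None or r.gene == gene)
        and r.classification in ("P", "LP")
        and r.evidence_ids
    ]
    if incl:
        sources.add("internal_inclusion")
    if pair.inclusion_list_only:
        return sources

    clinvar = [
        r for r in match_variant(variant, kb, "clinvar_like", allow_protein_match=True)
        if r.gene is None or r.gene == gene
    ]
    if aggregate_classifications(clinvar, thresholds.cip_mode):
        sources.add("clinvar_like")

    cva = [
        r for r in match_variant(variant, kb, "cva_like", allow_protein_match=True)
        if r.gene is None or r.gene == gene
    ]
    if any(r.classification in ("P", "LP") for r in cva):
        sources.add("cva_like")

    curated = [
        r for r in match_variant(
            variant, kb, "curated_commercial", allow_protein_match=False
        )
        if r.gene is None or r.gene == gene
    ]
    if any(r.classification in ("P", "LP") for r in curated):
        sources.add("curated_commercial")

    return sources


# ---------------------------------------------------------------------------
# predicted loss-of-function rules
# ---------------------------------------------------------------------------

def select_transcript(
    annotations: Sequence[TranscriptAnnotation], pair: GeneConditionPair
) -> TranscriptAnnotation | None:
    """Pick the reference transcript's annotation for a gene.

    Preference: MANE Select > MANE Clinical > predefined canonical; ties
    broken by longest coding sequence, then lexicographic transcript id.
    Returns None when no annotation carries a preferred-transcript flag
    (the variant is then ineligible for pLoF prioritization).
    """
    gene_anns = [a for a in annotations if a.gene_symbol == pair.gene_symbol]
    for flag in TRANSCRIPT_PREFERENCE:
        flagged = [a for a in gene_anns if flag in a.transcript_flags]
        if flagged:
            return min(
                flagged,
                key=lambda a: (-(a.cds_length or 0), a.transcript_id),
            )
    return None


def prioritize_plof_small(
    variant: NormalizedVariant,
    pair: GeneConditionPair,
    freqs: FrequencyReference,
    thresholds: Thresholds,
) -> bool:
    """Predicted loss-of-function rule for SNVs/indels/MNVs.

    Fires iff the gene's mechanism is loss of function, the reference
    transcript's annotation is high impact, and the variant is rare: every
    population tier below the per-MOI threshold and the internal AF below
    the configured pLoF limit. Absent frequencies count as rare.
    """
    if not pair.lof_mechanism or pair.inclusion_list_only:
        return False
    ann = select_transcript(variant.annotations, pair)
    if ann is None or ann.impact_class != "high":
        return False
    moi_key = thresholds.moi_key(pair.moi)
    af_max = thresholds.plof_af_max[moi_key]
    for af in freqs.population_for(variant).values():
        if af >= af_max:
            return False
    internal = freqs.internal_for(variant)
    internal_max = (
        af_max if thresholds.plof_internal_af_mode == "population"
        else thresholds.internal_af_max
    )
    if internal is not None and internal >= internal_max:
        return False
    return True


# ---------------------------------------------------------------------------
# CNV rules
# ---------------------------------------------------------------------------

def cnv_reference_frequency(
    cnv: CnvCall,
    reference_set: Sequence[tuple[CnvCall, float]],
    ro_threshold: float = 0.8,
) -> float:
    """Population frequency of a CNV against the reference set.

    Maximum frequency over same-type, same-contig reference events with
    reciprocal overlap >= ``ro_threshold``; 0.0 when nothing matches.
    """
    best = 0.0
    for ref_cnv, freq in reference_set:
        if ref_cnv.cnv_type != cnv.cnv_type or ref_cnv.contig != cnv.contig:
            continue
        if reciprocal_overlap(cnv.interval, ref_cnv.interval) >= ro_threshold:
            best = max(best, freq)
    return best


def prioritize_cnv(
    cnv: CnvCall,
    pair: GeneConditionPair,
    freqs: FrequencyReference,
    thresholds: Thresholds,
) -> bool:
    """Loss-of-function CNV rule (dosage/MOI pairing is left to moi_gate).

    Fires iff the gene's mechanism is loss of function and (i) the CNV
    padded by 2 kb intersects the gene's coding region, (ii) for gains both
    breakpoints fall within the reference transcript span, and (iii) the
    reference-set frequency at 80% reciprocal overlap is below the
    type-and-MOI threshold.
    """
    if not pair.lof_mechanism or pair.inclusion_list_only:
        return False
    if cnv.contig != pair.contig:
        return False
    padded = (cnv.start - thresholds.cnv_flank_bp, cnv.end + thresholds.cnv_flank_bp)
    if not any(intervals_intersect(padded, exon) for exon in pair.coding_region):
        return False
    if cnv.cnv_type == "gain":
        if not (pair.start <= cnv.start and cnv.end <= pair.end):
            return False
    freq = cnv_reference_frequency(
        cnv, freqs.cnv_reference, thresholds.cnv_recip_overlap
    )
    moi_key = thresholds.moi_key(pair.moi)
    limit = (
        thresholds.cnv_loss_af_max if cnv.cnv_type == "loss"
        else thresholds.cnv_gain_af_max
    )[moi_key]
    return freq < limit


def smn1_rule(result: SmnResult) -> bool:
    """Prioritize the case iff zero intact SMN1 copies are inferred."""
    if result.intact_smn1_copy_number < 0:
        raise ValueError("SMN1 copy number cannot be negative")
    return result.intact_smn1_copy_number == 0


# ---------------------------------------------------------------------------
# companion flags for complex alleles
# ---------------------------------------------------------------------------

def companion_flags(
    trigger_key: tuple,
    companion_table: Mapping[tuple, Sequence[tuple]] | None,
    sample_genotypes: Mapping[tuple, GenotypeCall],
) -> list[dict]:
    """Genotype reports for the configured companion variants of a trigger.

    Complex alleles are pathogenic only in specific combinations; when the
    trigger is prioritized, the reviewer needs the sample's genotype at
    each companion position (including "absent"). Never changes
    prioritization itself.
    """
    if not companion_table:
        return []
    reports = []
    for comp_key in companion_table.get(trigger_key, []):
        call = sample_genotypes.get(comp_key)
        reports.append({
            "companion": list(comp_key),
            "genotype": call.zygosity if call is not None else "absent",
        })
    return reports


# ---------------------------------------------------------------------------
# the full per-sample run
# ---------------------------------------------------------------------------

def run_sample(
    sample: SampleData,
    panel: Sequence[GeneConditionPair],
    kb: KnowledgeBase,
    exclusion: ExclusionList,
    freqs: FrequencyReference,
    thresholds: Thresholds | None = None,
    companions: Mapping[tuple, Sequence[tuple]] | None = None,
) -> list[PrioritizedCall]:
    """Run the full rule cascade for one sample.

    Universal filters -> per-source / pLoF / CNV candidate generation per
    gene-condition pair -> MOI gating with compound-het phasing ->
    companion flags. Deterministic; output ordered by genomic position.
    """
    if thresholds is None:
        thresholds = Thresholds()

    kept_variants = [
        (v, g) for v, g in sample.small_variants
        if universal_filter(v, exclusion)[0]
    ]
    kept_cnvs = [c for c in sample.cnvs if universal_filter(c, exclusion)[0]]
    sample_genotypes = {v.key: g for v, g in sample.small_variants}

    calls: list[PrioritizedCall] = []
    for pair in panel:
        candidates: list[_Candidate] = []
        for variant, geno in kept_variants:
            if not within_gene_window(variant, pair, thresholds.gene_window_bp):
                continue
            sources = prioritize_reported(variant, pair, kb, freqs, thresholds)
            if prioritize_plof_small(variant, pair, freqs, thresholds):
                sources.add("plof")
            if sources:
                candidates.append(
                    _Candidate(
                        payload=variant,
                        zygosity=geno.zygosity,
                        phase_set_id=geno.phase_set_id,
                        haplotype_index=geno.haplotype_index,
                        sources=sources,
                        position=variant.pos,
                    )
                )
        for cnv in kept_cnvs:
            if not prioritize_cnv(cnv, pair, freqs, thresholds):
                continue
            zygosity = "hom_alt" if cnv.copy_number == 0 else "het"
            cand = _Candidate(
                payload=cnv, zygosity=zygosity, phase_set_id=None,
                haplotype_index=None, sources={"cnv_plof"}, position=cnv.start,
            )
            if pair.moi != "monoallelic" and zygosity == "het" \
                    and not thresholds.cnv_comphet_with_snv:
                # het loss may not partner a het small variant: gate it alone
                continue
            candidates.append(cand)

        for group, rationale in moi_gate(
            candidates, pair.moi, thresholds.phasing_window_bp
        ):
            partner_keys = [c.key for c in group]
            for cand in group:
                flags = []
                if isinstance(cand.payload, NormalizedVariant):
                    flags = companion_flags(cand.key, companions, sample_genotypes)
                calls.append(
                    PrioritizedCall(
                        sample_id=sample.sample_id,
                        payload=cand.payload,
                        gene_condition=pair,
                        sources=frozenset(cand.sources),
                        zygosity_rationale=rationale,
                        companion_flags=flags,
                        comphet_partners=[
                            list(k) for k in partner_keys if k != cand.key
                        ],
                    )
                )

    if sample.smn is not None and smn1_rule(sample.smn):
        smn_pair = next(
            (p for p in panel if p.gene_symbol == "SMN1"), None
        )
        calls.append(
            PrioritizedCall(
                sample_id=sample.sample_id,
                payload=sample.smn,
                gene_condition=smn_pair,
                sources=frozenset({"smn1"}),
                zygosity_rationale="biallelic_hom",
            )
        )

    calls.sort(key=lambda c: c.sort_key())
    return calls


def run_cohort(
    samples: Sequence[SampleData],
    panel: Sequence[GeneConditionPair],
    kb: KnowledgeBase,
    exclusion: ExclusionList,
    freqs: FrequencyReference,
    thresholds: Thresholds | None = None,
    companions: Mapping[tuple, Sequence[tuple]] | None = None,
) -> dict[str, list[PrioritizedCall]]:
    """run_sample over a cohort; returns sample_id -> calls (every sample
    present, including those with no prioritized call)."""
    return {
        s.sample_id: run_sample(s, panel, kb, exclusion, freqs, thresholds, companions)
        for s in samples
    }


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "sample", "contig", "pos", "ref", "alt", "cnv_type", "start", "end",
    "gene", "condition", "moi", "sources", "zygosity_rationale",
    "comphet_partners", "companion_flags",
]


def calls_to_frame(calls_by_sample: Mapping[str, Sequence[PrioritizedCall]]) -> pd.DataFrame:
    """Flatten prioritized calls into the tabular report layout."""
    rows = []
    for sample_id in sorted(calls_by_sample):
        for call in calls_by_sample[sample_id]:
            row = {c: "" for c in REPORT_COLUMNS}
            row["sample"] = sample_id
            pair = call.gene_condition
            if pair is not None:
                row["gene"] = pair.gene_symbol
                row["condition"] = pair.condition_id
                row["moi"] = pair.moi
            payload = call.payload
            if isinstance(payload, NormalizedVariant):
                row.update(contig=payload.contig, pos=payload.pos,
                           ref=payload.ref, alt=payload.alt)
            elif isinstance(payload, CnvCall):
                row.update(contig=payload.contig, cnv_type=payload.cnv_type,
                           start=payload.start, end=payload.end)
            else:
                row["cnv_type"] = "smn1_zero_copies"
            row["sources"] = ",".join(sorted(call.sources))
            row["zygosity_rationale"] = call.zygosity_rationale
            row["comphet_partners"] = json.dumps(call.comphet_partners)
            row["companion_flags"] = json.dumps(call.companion_flags)
            rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    calls_by_sample: Mapping[str, Sequence[PrioritizedCall]],
    tsv_path: str | Path,
    jsonl_path: str | Path | None = None,
) -> None:
    df = calls_to_frame(calls_by_sample)
    df.to_csv(tsv_path, sep="\t", index=False)
    if jsonl_path is not None:
        with open(jsonl_path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
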