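"""Panel definition, pathogenicity knowledge bases, and frequency references.

The screening panel is a table of gene-condition pairs, each carrying a mode
of inheritance (MOI), a loss-of-function mechanism flag, and the evidence
sources enabled for it. Classification evidence comes from four source
kinds with distinct eligibility rules:

* ``clinvar_like``   — public archive; protein matching allowed; the
  conflicting-interpretation (CIP) policy applies here.
* ``cva_like``       — interpretation outcomes from prior clinical cases;
  protein matching allowed; any P/LP record qualifies.
* ``curated_commercial`` — single curated classification per variant;
  coordinate matching only.
* ``internal_inclusion`` — hand-curated inclusion lists; coordinate
  matching only; every record must cite PubMed evidence. Twelve-gene-style
  "inclusion-list-only" panel entries disable all other sources.

An exclusion list (artefacts, low-penetrance alleles, out-of-scope
conditions, complex-allele components) always wins over every source.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import (
    GenotypeCall,
    NormalizedVariant,
    decompose_mnv,
    normalize_contig,
    normalize_protein_change,
    normalize_variant,
)

SOURCES = ("clinvar_like", "cva_like", "curated_commercial", "internal_inclusion")
PROTEIN_MATCH_SOURCES = frozenset({"clinvar_like", "cva_like"})

VALID_MOI = ("monoallelic", "biallelic", "x_linked")

P_LP = frozenset({"P", "LP"})
B_LB = frozenset({"B", "LB"})

CIP_MODES = ("none", "p_and_no_b", "p_and_le1_b", "le1_b", "all")

EXCLUSION_REASONS = (
    "artefact",
    "low_penetrance",
    "condition_not_in_study",
    "overlapping_gene",
    "complex_allele_component",
)


def canonical_classification(label: str) -> str:
    """Map assorted classification spellings onto {P, LP, VUS, LB, B}.

    Composite "pathogenic/likely pathogenic" labels count as P.
    """
    s = str(label).strip().lower().replace("_", " ")
    if s in ("p", "pathogenic", "pathogenic/likely pathogenic"):
        return "P"
    if s in ("lp", "likely pathogenic"):
        return "LP"
    if s in ("b", "benign", "benign/likely benign"):
        return "B"
    if s in ("lb", "likely benign"):
        return "LB"
    if s in ("vus", "uncertain significance", "uncertain"):
        return "VUS"
    raise ValueError(f"unrecognized classification label {label!r}")


@dataclass(frozen=True)
class GeneConditionPair:
    """One panel entry: a gene screened for one condition under one MOI."""

    gene_symbol: str
    condition_id: str
    moi: str  # monoallelic | biallelic | x_linked
    lof_mechanism: bool
    inclusion_list_only: bool
    contig: str
    start: int
    end: int
    transcript: str
    coding_exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.moi not in VALID_MOI:
            raise ValueError(f"invalid MOI {self.moi!r}")
        if self.start > self.end:
            raise ValueError("gene span start must be <= end")

    @property
    def gene_span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def coding_region(self) -> tuple[tuple[int, int], ...]:
        """Coding exons of the reference transcript; falls back to the
        whole gene span when no exon model is configured."""
        return self.coding_exons if self.coding_exons else ((self.start, self.end),)


@dataclass(frozen=True)
class ClassificationRecord:
    """One knowledge-base assertion about a variant or a protein change."""

    source: str
    classification: str  # P | LP | VUS | LB | B
    gene: str | None = None
    variant_key: tuple[str, int, str, str] | None = None
    protein_change: str | None = None
    evidence_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        object.__setattr__(
            self, "classification", canonical_classification(self.classification)
        )
        object.__setattr__(
            self, "protein_change", normalize_protein_change(self.protein_change)
        )
        if self.source == "internal_inclusion" and not self.evidence_ids:
            raise ValueError("internal inclusion records require PubMed evidence ids")


@dataclass(frozen=True)
class ExclusionEntry:
    variant_key: tuple[str, int, str, str]
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


@dataclass
class Thresholds:
    """All tunable policy values of the prioritization pipeline.

    Allele-frequency limits are fractions in (0, 1); windows and flanks are
    base pairs. The pLoF population-AF limits are per mode of inheritance
    (x-linked genes use the stricter monoallelic values).
    """

    internal_af_max: float = 0.05
    plof_af_max: dict = field(
        default_factory=lambda: {"monoallelic": 1e-4, "biallelic": 5e-3}
    )
    #: whether the internal-AF gate for pLoF candidates uses the per-MOI
    #: population thresholds ("population") or the reported-variant 0.05
    #: cut-off ("reported")
    plof_internal_af_mode: str = "population"
    cnv_loss_af_max: dict = field(
        default_factory=lambda: {"monoallelic": 0.001, "biallelic": 0.005}
    )
    cnv_gain_af_max: dict = field(
        default_factory=lambda: {"monoallelic": 0.002, "biallelic": 0.01}
    )
    cnv_recip_overlap: float = 0.8
    cnv_flank_bp: int = 2000
    gene_window_bp: int = 50
    phasing_window_bp: int = 150
    coverage_min_depth: int = 15
    coverage_mean_median_min: float = 30.0
    coverage_poor_fraction: float = 0.95
    callability_compromised_fraction: float = 0.5
    wilson_z: float = 1.96
    cip_mode: str = "p_and_le1_b"
    #: whether a prioritized CNV loss may pair with a het small variant to
    #: satisfy a biallelic MOI
    cnv_comphet_with_snv: bool = True
    high_impact_consequences: tuple = (
        "stop_gained", "frameshift_variant", "frameshift",
        "splice_acceptor_variant", "splice_donor_variant",
        "start_lost", "stop_lost", "transcript_ablation",
    )

    def __post_init__(self) -> None:
        if self.cip_mode not in CIP_MODES:
            raise ValueError(f"invalid cip_mode {self.cip_mode!r}")
        for name in ("internal_af_max",):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1)")

    def moi_key(self, moi: str) -> str:
        return "monoallelic" if moi in ("monoallelic", "x_linked") else "biallelic"

    def replace(self, **changes) -> "Thresholds":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["high_impact_consequences"] = list(self.high_impact_consequences)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Thresholds":
        kwargs = dict(d)
        if "high_impact_consequences" in kwargs:
            kwargs["high_impact_consequences"] = tuple(kwargs["high_impact_consequences"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# knowledge-base container and matching
# ---------------------------------------------------------------------------

class KnowledgeBase:
    """Classification records indexed by exact variant key and by
    (gene, protein change), per source."""

    def __init__(self, records: Iterable[ClassificationRecord] = ()):
        self._by_key: dict[str, dict[tuple, list[ClassificationRecord]]] = {
            s: {} for s in SOURCES
        }
        self._by_protein: dict[str, dict[tuple, list[ClassificationRecord]]] = {
            s: {} for s in SOURCES
        }
        self.records: list[ClassificationRecord] = []
        for rec in records:
            self.add(rec)

    def add(self, rec: ClassificationRecord) -> None:
        self.records.append(rec)
        if rec.variant_key is not None:
            self._by_key[rec.source].setdefault(rec.variant_key, []).append(rec)
        if rec.protein_change is not None and rec.gene is not None:
            pkey = (rec.gene, rec.protein_change)
            self._by_protein[rec.source].setdefault(pkey, []).append(rec)

    def exact(self, source: str, key: tuple) -> list[ClassificationRecord]:
        return list(self._by_key[source].get(key, []))

    def by_protein(self, source: str, gene: str, change: str) -> list[ClassificationRecord]:
        change = normalize_protein_change(change)
        return list(self._by_protein[source].get((gene, change), []))


def match_variant(
    variant: NormalizedVariant,
    kb: KnowledgeBase,
    source: str,
    allow_protein_match: bool = True,
) -> list[ClassificationRecord]:
    """Return the source's records matching a variant.

    Exact coordinate-and-allele matches are always returned. Protein-change
    matches (same gene, same normalized p. change) are added only when
    requested, the source supports them, and the variant is not an MNV —
    protein matching is unreliable for MNVs because the decomposed SNVs
    imply different protein changes than the joint allele.
    """
    records = kb.exact(source, variant.key)
    if (
        allow_protein_match
        and source in PROTEIN_MATCH_SOURCES
        and variant.variant_class != "mnv"
    ):
        seen = {id(r) for r in records}
        for ann in variant.annotations:
            if ann.protein_change is None:
                continue
            for rec in kb.by_protein(source, ann.gene_symbol, ann.protein_change):
                if id(rec) not in seen:
                    records.append(rec)
                    seen.add(id(rec))
    return records


def aggregate_classifications(
    records: Sequence[ClassificationRecord],
    cip_mode: str = "p_and_le1_b",
) -> bool:
    """Decide source eligibility from a set of classification records.

    A variant whose records span more than one of the categories
    {P/LP, VUS, B/LB} has conflicting interpretations of pathogenicity
    (CIP); the ``cip_mode`` scenario then decides eligibility:

    ========================  =============================================
    none                      CIP variants never eligible
    p_and_no_b                >=1 P/LP and 0 B/LB
    p_and_le1_b (default)     >=1 P/LP and <=1 B/LB
    le1_b                     <=1 B/LB (no P/LP requirement)
    all                       every CIP variant eligible
    ========================  =============================================

    Concordant variants are eligible iff all records are P/LP. The scenario
    chain none < p_and_no_b < p_and_le1_b < le1_b < all is a containment
    chain: each mode's eligible set includes the previous mode's.
    """
    if cip_mode not in CIP_MODES:
        raise ValueError(f"invalid cip_mode {cip_mode!r}")
    if not records:
        return False
    n_plp = sum(1 for r in records if r.classification in P_LP)
    n_blb = sum(1 for r in records if r.classification in B_LB)
    n_vus = len(records) - n_plp - n_blb
    categories = sum(1 for n in (n_plp, n_blb, n_vus) if n > 0)
    if categories <= 1:
        return n_plp > 0  # concordant: all-P/LP qualifies, all-VUS / all-B does not
    if cip_mode == "none":
        return False
    if cip_mode == "p_and_no_b":
        return n_plp >= 1 and n_blb == 0
    if cip_mode == "p_and_le1_b":
        return n_plp >= 1 and n_blb <= 1
    if cip_mode == "le1_b":
        return n_blb <= 1
    return True  # "all"


class ExclusionList:
    """Coordinate-and-allele exact exclusion set; exclusion always wins."""

    def __init__(self, entries: Iterable[ExclusionEntry] = ()):
        self._entries: dict[tuple, str] = {}
        for e in entries:
            self._entries[e.variant_key] = e.reason

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.items())

    def lookup(self, key: tuple) -> str | None:
        return self._entries.get(key)


def is_excluded(key: tuple, exclusion: ExclusionList) -> tuple[bool, str | None]:
    """Exact coordinate-and-allele membership test against the exclusion
    list; a different alt at the same position is not excluded."""
    reason = exclusion.lookup(key)
    return (reason is not None), reason


def within_gene_window(
    variant: NormalizedVariant, pair: GeneConditionPair, window_bp: int = 50
) -> bool:
    """True iff the variant's reference footprint intersects the gene span
    padded by ``window_bp`` on both sides."""
    if variant.contig != pair.contig:
        return False
    lo = pair.start - window_bp
    hi = pair.end + window_bp
    return variant.pos <= hi and variant.end >= lo


def internal_af(
    calls: Sequence[GenotypeCall], n_samples: int, diploid: bool = True
) -> float | None:
    """Cohort alternate-allele frequency for one variant.

    hom_alt contributes 2 alleles, het 1, hemi 1 (against a haploid
    denominator contribution). Returns None (undefined) when no alleles
    were callable; undefined frequencies pass rarity filters downstream
    (absent means rare).
    """
    if n_samples <= 0:
        return None
    ploidy = 2 if diploid else 1
    total = n_samples * ploidy
    alt = 0
    for c in calls:
        if c.zygosity == "hom_alt":
            alt += 2
        elif c.zygosity in ("het", "hemi"):
            alt += 1
    if total == 0:
        return None
    return alt / total


@dataclass
class FrequencyReference:
    """Internal-cohort AFs, per-tier population AFs, and the CNV frequency
    reference set (entries as (CnvCall, frequency))."""

    internal: dict = field(default_factory=dict)  # key -> af
    population: dict = field(default_factory=dict)  # key -> {tier: af}
    cnv_reference: list = field(default_factory=list)  # [(CnvCall, freq)]

    def internal_for(self, variant: NormalizedVariant) -> float | None:
        """Internal AF; MNVs use the minimum over their decomposed SNVs.
        None when the variant (or all its decomposed SNVs) is absent."""
        if variant.variant_class == "mnv":
            afs = [
                self.internal.get(s.key)
                for s in decompose_mnv(variant)
            ]
            afs = [a for a in afs if a is not None]
            return min(afs) if afs else None
        return self.internal.get(variant.key)

    def population_for(self, variant: NormalizedVariant) -> dict:
        """Per-tier population AFs; MNVs take the per-tier minimum over
        decomposed SNVs. Absent tiers are omitted (absent means rare)."""
        if variant.variant_class != "mnv":
            return dict(self.population.get(variant.key, {}))
        merged: dict[str, float] = {}
        for snv in decompose_mnv(variant):
            for tier, af in self.population.get(snv.key, {}).items():
                if tier not in merged or af < merged[tier]:
                    merged[tier] = af
        return merged


# ---------------------------------------------------------------------------
# file loaders (TSV interfaces)
# ---------------------------------------------------------------------------

def _parse_exons(text: str) -> tuple[tuple[int, int], ...]:
    text = str(text).strip()
    if not text or text.lower() == "nan":
        return ()
    out = []
    for part in text.split(";"):
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return tuple(out)


def load_panel(path: str | Path) -> list[GeneConditionPair]:
    """Load the gene-condition panel from TSV: gene, condition, moi,
    lof_mechanism, inclusion_list_only, contig, start, end, transcript
    and optionally coding_exons ("start-end;start-end")."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    pairs = []
    for row in df.itertuples(index=False):
        contig = normalize_contig(row.contig)
        if contig is None:
            raise ValueError(f"panel gene {row.gene} on unsupported contig {row.contig}")
        pairs.append(
            GeneConditionPair(
                gene_symbol=row.gene,
                condition_id=row.condition,
                moi=row.moi,
                lof_mechanism=_parse_bool(row.lof_mechanism),
                inclusion_list_only=_parse_bool(row.inclusion_list_only),
                contig=contig,
                start=int(row.start),
                end=int(row.end),
                transcript=row.transcript,
                coding_exons=_parse_exons(getattr(row, "coding_exons", "")),
            )
        )
    return pairs


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in ("1", "true", "yes")


def load_knowledge(path: str | Path) -> KnowledgeBase:
    """Load classification records from TSV: source, contig, pos, ref, alt,
    gene, protein_change, classification, evidence_ids (comma-joined).
    Coordinate columns may be empty for protein-key-only records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    kb = KnowledgeBase()
    for row in df.itertuples(index=False):
        key = None
        if str(row.contig).strip() and str(row.pos).strip():
            v = normalize_variant(row.contig, int(row.pos), row.ref, row.alt)
            key = v.key
        evidence = tuple(e for e in str(row.evidence_ids).split(",") if e.strip())
        kb.add(
            ClassificationRecord(
                source=row.source,
                classification=row.classification,
                gene=row.gene or None,
                variant_key=key,
                protein_change=row.protein_change or None,
                evidence_ids=evidence,
            )
        )
    return kb


def load_exclusion(path: str | Path) -> ExclusionList:
    """Load the exclusion list from TSV: contig, pos, ref, alt, reason."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        v = normalize_variant(row.contig, int(row.pos), row.ref, row.alt)
        entries.append(ExclusionEntry(variant_key=v.key, reason=row.reason))
    return ExclusionList(entries)


def load_frequencies(
    internal_path: str | Path | None = None,
    population_path: str | Path | None = None,
    cnv_reference_path: str | Path | None = None,
) -> FrequencyReference:
    """Assemble a FrequencyReference from its TSV components.

    internal: contig, pos, ref, alt, af. population: contig, pos, ref, alt,
    tier, af (long format). cnv reference: contig, start, end, type,
    frequency.
    """
    from .datamodel import CnvCall  # local import keeps module load order simple

    ref = FrequencyReference()
    if internal_path is not None:
        df = pd.read_csv(internal_path, sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            v = normalize_variant(row.contig, int(row.pos), row.ref, row.alt)
            ref.internal[v.key] = float(row.af)
    if population_path is not None:
        df = pd.read_csv(population_path, sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            v = normalize_variant(row.contig, int(row.pos), row.ref, row.alt)
            ref.population.setdefault(v.key, {})[row.tier] = float(row.af)
    if cnv_reference_path is not None:
        df = pd.read_csv(cnv_reference_path, sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            contig = normalize_contig(row.contig)
            if contig is None:
                continue
            call = CnvCall(
                contig=contig, start=int(row.start), end=int(row.end),
                cnv_type=str(row.type),
            )
            ref.cnv_reference.append((call, float(row.frequency)))
    return ref


def load_companions(path: str | Path) -> dict[tuple, list[tuple]]:
    """Load the companion-variant table: trigger (contig, pos, ref, alt) ->
    companion (contig2, pos2, ref2, alt2); multiple companions per trigger
    allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table: dict[tuple, list[tuple]] = {}
    for row in df.itertuples(index=False):
        trig = normalize_variant(row.contig, int(row.pos), row.ref, row.alt).key
        comp = normalize_variant(row.contig2, int(row.pos2), row.ref2, row.alt2).key
        table.setdefault(trig, []).append(comp)
    return table


def overlap_exclusion_candidates(
    kb: KnowledgeBase,
    panel: Sequence[GeneConditionPair],
    window_bp: int = 50,
) -> list[ExclusionEntry]:
    """Propose exclusion entries for knowledge-base records that fall inside
    a *different* panel gene's padded span.

    Coordinate-and-allele matching cannot tell overlapping genes apart, so
    records attributed to one gene but located within another panel gene
    are emitted as candidates for curation (reason ``overlapping_gene``).
    """
    candidates: dict[tuple, ExclusionEntry] = {}
    for rec in kb.records:
        if rec.variant_key is None or rec.gene is None:
            continue
        contig, pos, ref, _alt = rec.variant_key
        end = pos + len(ref) - 1
        for pair in panel:
            if pair.gene_symbol == rec.gene or pair.contig != contig:
                continue
            if pos <= pair.end + window_bp and end >= pair.start - window_bp:
                candidates[rec.variant_key] = ExclusionEntry(
                    variant_key=rec.variant_key, reason="overlapping_gene"
                )
                break
    return sorted(candidates.values(), key=lambda e: e.variant_key)
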