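"""Core variant and CNV data model, normalization, and format I/O.

Small variants are held as minimal, left-aligned alleles on 1-based
coordinates (VCF convention) so that coordinate-and-allele matching against
knowledge bases, inclusion lists, and exclusion lists is well defined.
Multi-allelic records are split before anything downstream sees them, and
only chromosomes 1-22 and X are retained (mitochondrial and alternate
contigs carry no screened conditions).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("nbscreen")

ALLOWED_CONTIGS = tuple(str(i) for i in range(1, 23)) + ("X",)
_ACGT = frozenset("ACGT")

VALID_ZYGOSITY = ("het", "hom_alt", "hemi")
VALID_CNV_TYPES = ("loss", "gain")

#: minimum event size (bp) for a copy-number call to be considered at all
CNV_MIN_LENGTH = 2000
#: above this size a CNV call's own filter status is trusted as-is
CNV_TRUSTED_LENGTH = 10_000
#: reciprocal overlap required for SV-caller confirmation of 2-10 kb CNVs
CNV_CONFIRM_RO = 0.5

_AA_1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter", "X": "Xaa",
}


class VariantFormatError(ValueError):
    """Raised for alleles containing characters outside {A, C, G, T}."""


class DegenerateVariantError(ValueError):
    """Raised when ref and alt describe no change."""


def normalize_contig(contig: str) -> str | None:
    """Map a contig name onto the supported set, or None if unsupported.

    Accepts "chr"-prefixed aliases ("chrX" == "X", "chr7" == "7").
    """
    name = str(contig)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() == "X":
        name = "X"
    return name if name in ALLOWED_CONTIGS else None


def normalize_protein_change(change: str | None) -> str | None:
    """Canonicalize a protein-change string for equality matching.

    Strips the "p." prefix and surrounding parentheses and converts
    one-letter substitutions to three-letter notation, so that e.g.
    "p.(R100*)", "p.Arg100Ter" and "R100*" all compare equal.
    """
    if change is None:
        return None
    s = str(change).strip()
    if not s or s.lower() in ("nan", "none", "."):
        return None
    if s.lower().startswith("p."):
        s = s[2:]
    s = s.strip("()")
    m = re.fullmatch(r"([A-Z*])(\d+)([A-Z*])", s)
    if m and m.group(1) in _AA_1TO3 and m.group(3) in _AA_1TO3:
        s = f"{_AA_1TO3[m.group(1)]}{m.group(2)}{_AA_1TO3[m.group(3)]}"
    return s


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript-level consequence annotation for a variant."""

    gene_symbol: str
    transcript_id: str
    consequence_terms: tuple[str, ...]
    impact_class: str  # high | moderate | low | modifier
    protein_change: str | None = None
    transcript_flags: frozenset[str] = frozenset()
    cds_length: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "protein_change", normalize_protein_change(self.protein_change)
        )


@dataclass
class NormalizedVariant:
    """A left-aligned, minimally represented small-variant allele."""

    contig: str
    pos: int
    ref: str
    alt: str
    variant_class: str = ""  # snv | indel | mnv
    annotations: list[TranscriptAnnotation] = field(default_factory=list)
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if not self.variant_class:
            self.variant_class = classify_alleles(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last reference base touched (1-based inclusive)."""
        return self.pos + len(self.ref) - 1

    @property
    def is_pass(self) -> bool:
        return self.filter_status == "PASS"

    def annotations_for_gene(self, gene_symbol: str) -> list[TranscriptAnnotation]:
        return [a for a in self.annotations if a.gene_symbol == gene_symbol]


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype for one normalized allele."""

    sample_id: str
    variant_key: tuple[str, int, str, str]
    zygosity: str  # het | hom_alt | hemi
    phase_set_id: str | None = None
    haplotype_index: int | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in VALID_ZYGOSITY:
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.haplotype_index is not None and self.phase_set_id is None:
            raise ValueError("haplotype_index requires a phase_set_id")


@dataclass
class CnvCall:
    """A copy-number event (loss or gain) with its span and filter status.

    Coordinates are 1-based inclusive; events of 2 kb or less are outside
    the detection contract and rejected on construction.
    """

    contig: str
    start: int
    end: int
    cnv_type: str  # loss | gain
    filter_status: str = "PASS"
    caller_support: frozenset[str] = frozenset({"cnv_caller"})
    copy_number: int | None = None  # 0 marks a homozygous loss

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CNV start must be <= end")
        if self.cnv_type not in VALID_CNV_TYPES:
            raise ValueError(f"invalid cnv_type {self.cnv_type!r}")
        if self.length <= CNV_MIN_LENGTH:
            raise ValueError(f"CNV length {self.length} must exceed {CNV_MIN_LENGTH} bp")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def is_pass(self) -> bool:
        return self.filter_status == "PASS"

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.cnv_type)


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    if len(ref) == len(alt):
        return "mnv"
    return "indel"


def normalize_variant(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str] | str | None = None,
) -> NormalizedVariant:
    """Return the minimal, left-aligned representation of an allele.

    Shared prefix/suffix bases are trimmed; when ``reference`` supplies the
    contig sequence, indels are additionally shifted to their leftmost
    equivalent position (full left-alignment). The operation is idempotent.

    Parameters
    ----------
    reference
        Either the contig sequence itself or a mapping contig -> sequence
        (1-based position ``p`` is ``seq[p-1]``). Without it only
        prefix/suffix trimming is performed.
    """
    ref, alt = str(ref).upper(), str(alt).upper()
    if not ref or not alt or not (_ACGT >= set(ref)) or not (_ACGT >= set(alt)):
        raise VariantFormatError(f"alleles must be nonempty ACGT strings: {ref!r}/{alt!r}")
    if ref == alt:
        raise DegenerateVariantError(f"ref == alt at {contig}:{pos} ({ref})")
    if pos < 1:
        raise VariantFormatError(f"position must be >= 1, got {pos}")
    norm_contig = normalize_contig(contig)
    contig = norm_contig if norm_contig is not None else str(contig)
    pos = int(pos)

    seq: str | None = None
    if reference is not None:
        seq = reference if isinstance(reference, str) else reference.get(contig)

    if seq is None:
        # trim shared suffix then prefix; keeps at least one base per allele
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
    else:
        # vt-style left alignment against the reference sequence
        while True:
            if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
                ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    # cannot shift further left: re-anchor by extending to
                    # the right so ref stays a true reference substring
                    base = seq[len(ref)].upper()
                    ref, alt = ref + base, alt + base
                    break
                base = seq[pos - 2].upper()
                ref, alt = base + ref, base + alt
                pos -= 1
                continue
            if ref[-1] != alt[-1] or (len(ref) == 1 and len(alt) == 1):
                break
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
    return NormalizedVariant(contig=contig, pos=pos, ref=ref, alt=alt)


def decompose_mnv(v: NormalizedVariant) -> list[NormalizedVariant]:
    """Split a multi-nucleotide variant into its constituent SNVs.

    One SNV is emitted per position where ref and alt differ; frequency
    filters on MNVs operate on the minimum over these SNVs.
    """
    if v.variant_class != "mnv":
        raise ValueError(f"decompose_mnv requires an MNV, got {v.variant_class}")
    out = []
    for i, (r, a) in enumerate(zip(v.ref, v.alt)):
        if r != a:
            snv = NormalizedVariant(
                contig=v.contig, pos=v.pos + i, ref=r, alt=a,
                annotations=v.annotations, filter_status=v.filter_status,
            )
            out.append(snv)
    return out


# ---------------------------------------------------------------------------
# interval arithmetic (shared by CNV merging and the rule engine)
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap of two 1-based inclusive intervals.

    min(overlap/len(a), overlap/len(b)); 0.0 when disjoint.
    """
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    len_a = a[1] - a[0] + 1
    len_b = b[1] - b[0] + 1
    return min(ov / len_a, ov / len_b)


def intervals_intersect(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def merge_cnv_calls(
    cnv_calls: Sequence[CnvCall],
    sv_calls: Sequence[CnvCall],
    min_ro: float = CNV_CONFIRM_RO,
) -> list[CnvCall]:
    """Combine CNV-caller and SV-caller output into quality-resolved calls.

    Calls longer than 10 kb keep the CNV caller's own filter status. Calls
    of 2-10 kb are set to PASS only when a same-type SV-caller call confirms
    them at >= ``min_ro`` reciprocal overlap; unconfirmed mid-size calls are
    demoted to "LowSupport" (or keep their original non-PASS status).
    """
    out: list[CnvCall] = []
    for cnv in cnv_calls:
        if cnv.length > CNV_TRUSTED_LENGTH:
            out.append(cnv)
            continue
        confirmed = any(
            sv.cnv_type == cnv.cnv_type
            and sv.contig == cnv.contig
            and reciprocal_overlap(cnv.interval, sv.interval) >= min_ro
            for sv in sv_calls
        )
        if confirmed:
            out.append(
                CnvCall(
                    contig=cnv.contig, start=cnv.start, end=cnv.end,
                    cnv_type=cnv.cnv_type, filter_status="PASS",
                    caller_support=cnv.caller_support | {"sv_caller"},
                    copy_number=cnv.copy_number,
                )
            )
        else:
            status = cnv.filter_status if cnv.filter_status != "PASS" else "LowSupport"
            out.append(
                CnvCall(
                    contig=cnv.contig, start=cnv.start, end=cnv.end,
                    cnv_type=cnv.cnv_type, filter_status=status,
                    caller_support=cnv.caller_support, copy_number=cnv.copy_number,
                )
            )
    return out


# ---------------------------------------------------------------------------
# annotation sidecar
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "contig", "pos", "ref", "alt", "gene", "transcript",
    "consequence", "impact", "protein_change", "flags", "cds_length",
]


def read_annotation_table(path: str | Path) -> dict[tuple, list[TranscriptAnnotation]]:
    """Read a sidecar annotation TSV keyed by (contig, pos, ref, alt).

    Columns: contig, pos, ref, alt, gene, transcript, consequence
    ("&"-joined terms), impact, protein_change, flags ("&"-joined), and
    optionally cds_length. Keys are normalized on read so lookups from
    normalized variants succeed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table: dict[tuple, list[TranscriptAnnotation]] = {}
    for row in df.itertuples(index=False):
        v = normalize_variant(row.contig, int(row.pos), row.ref, row.alt)
        flags = frozenset(f for f in str(row.flags).split("&") if f)
        cds = getattr(row, "cds_length", "")
        ann = TranscriptAnnotation(
            gene_symbol=row.gene,
            transcript_id=row.transcript,
            consequence_terms=tuple(t for t in str(row.consequence).split("&") if t),
            impact_class=row.impact,
            protein_change=row.protein_change or None,
            transcript_flags=flags,
            cds_length=int(cds) if str(cds).strip() else None,
        )
        table.setdefault(v.key, []).append(ann)
    return table


# ---------------------------------------------------------------------------
# VCF reading and writing
# ---------------------------------------------------------------------------

def read_small_variant_vcf(
    path: str | Path,
    annotations: Mapping[tuple, list[TranscriptAnnotation]] | None = None,
) -> Iterator[tuple[NormalizedVariant, GenotypeCall]]:
    """Stream (variant, genotype) pairs from a VCF.

    Multi-allelic records are split and each allele normalized; contigs
    outside 1-22/X are dropped; FILTER is preserved on the variant. One
    GenotypeCall is yielded per sample carrying the allele. Records with
    no usable genotype are skipped with a warning.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for rec in vcf:
        contig = normalize_contig(rec.CHROM)
        if contig is None:
            continue
        filt = rec.FILTER or "PASS"  # cyvcf2 reports PASS as None
        genotypes = rec.genotypes
        if not genotypes:
            logger.warning("record %s:%s has no genotypes; skipped", rec.CHROM, rec.POS)
            continue
        ps_values = _format_field(rec, "PS")
        for allele_index, alt in enumerate(rec.ALT, start=1):
            if not alt or not (_ACGT >= set(alt.upper())):
                continue  # symbolic / spanning-deletion alleles
            try:
                variant = normalize_variant(contig, rec.POS, rec.REF, alt)
            except (VariantFormatError, DegenerateVariantError):
                logger.warning("unparseable allele at %s:%s; skipped", rec.CHROM, rec.POS)
                continue
            variant.filter_status = filt
            if annotations is not None:
                variant.annotations = list(annotations.get(variant.key, []))
            for si, sample in enumerate(samples):
                gt = genotypes[si]
                alleles = [a for a in gt[:-1] if a >= 0]
                phased = bool(gt[-1])
                if not alleles:
                    continue  # missing genotype for this sample
                count = sum(1 for a in alleles if a == allele_index)
                if count == 0:
                    continue
                if len(alleles) == 1:
                    zygosity = "hemi"
                elif count == len(alleles):
                    zygosity = "hom_alt"
                else:
                    zygosity = "het"
                ps = None
                hap = None
                if ps_values is not None and _ps_present(ps_values[si]):
                    ps = f"{contig}:{ps_values[si]}"
                    if phased and zygosity == "het":
                        hap = next(
                            i for i, a in enumerate(gt[:-1]) if a == allele_index
                        )
                yield variant, GenotypeCall(
                    sample_id=sample,
                    variant_key=variant.key,
                    zygosity=zygosity,
                    phase_set_id=ps,
                    haplotype_index=hap,
                )


def _ps_present(value) -> bool:
    """cyvcf2 encodes a missing integer FORMAT value as INT32_MIN."""
    s = str(value)
    if s in (".", ""):
        return False
    try:
        return int(s) >= 0
    except ValueError:
        return True


def _format_field(rec, tag: str):
    try:
        arr = rec.format(tag)
    except KeyError:
        return None
    if arr is None:
        return None
    return [row[0] if hasattr(row, "__len__") else row for row in arr]


_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
"""


def write_small_variant_vcf(
    path: str | Path,
    records: Iterable[tuple[NormalizedVariant, Mapping[str, GenotypeCall]]],
    samples: Sequence[str],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write variants with per-sample genotypes to an uncompressed VCF.

    Samples without a GenotypeCall for a record are written as 0/0. Phased
    het genotypes are written with "|" and a PS value; everything else
    unphased. Inverse of :func:`read_small_variant_vcf` on supported input.
    """
    lines = [_VCF_HEADER]
    if contig_lengths:
        for contig, length in contig_lengths.items():
            lines.append(f"##contig=<ID={contig},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
    for variant, calls in records:
        fields = [
            variant.contig, str(variant.pos), ".", variant.ref, variant.alt,
            ".", variant.filter_status, ".", "GT:PS",
        ]
        for sample in samples:
            call = calls.get(sample)
            if call is None:
                fields.append("0/0:.")
                continue
            ps = "."
            if call.zygosity == "hemi":
                gt = "1"
            elif call.zygosity == "hom_alt":
                gt = "1/1"
            elif call.haplotype_index is not None:
                gt = "0|1" if call.haplotype_index == 1 else "1|0"
                ps = call.phase_set_id.split(":")[-1]
            else:
                gt = "0/1"
                if call.phase_set_id is not None:
                    ps = call.phase_set_id.split(":")[-1]
            fields.append(f"{gt}:{ps}")
        lines.append("\t".join(fields) + "\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# CNV input
# ---------------------------------------------------------------------------

def read_cnv_tsv(path: str | Path) -> pd.DataFrame:
    """Read CNV calls from a TSV: sample, contig, start, end, type, filter
    and optionally copy_number. Returns the raw table; use
    :func:`cnv_calls_from_frame` to materialize CnvCall objects."""
    return pd.read_csv(path, sep="\t", dtype={"contig": str}, keep_default_na=False)


def cnv_calls_from_frame(df: pd.DataFrame) -> dict[str, list[CnvCall]]:
    """Group a CNV table into per-sample CnvCall lists, dropping
    unsupported contigs and sub-2-kb events."""
    by_sample: dict[str, list[CnvCall]] = {}
    for row in df.itertuples(index=False):
        contig = normalize_contig(row.contig)
        if contig is None:
            continue
        length = int(row.end) - int(row.start) + 1
        if length <= CNV_MIN_LENGTH:
            continue
        cn = getattr(row, "copy_number", "")
        call = CnvCall(
            contig=contig,
            start=int(row.start),
            end=int(row.end),
            cnv_type=str(row.type),
            filter_status=str(row.filter),
            copy_number=int(cn) if str(cn).strip() else None,
        )
        by_sample.setdefault(str(row.sample), []).append(call)
    return by_sample


def read_cnv_vcf(path: str | Path, sample_id: str | None = None) -> list[CnvCall]:
    """Read CNV/SV calls from VCF records carrying SVTYPE (DEL/DUP) and END."""
    vcf = VCF(str(path))
    if sample_id is None and vcf.samples:
        sample_id = vcf.samples[0]
    out: list[CnvCall] = []
    for rec in vcf:
        contig = normalize_contig(rec.CHROM)
        if contig is None:
            continue
        svtype = rec.INFO.get("SVTYPE")
        if svtype not in ("DEL", "DUP"):
            continue
        end = rec.INFO.get("END")
        if end is None:
            continue
        start, end = rec.POS, int(end)
        if end - start + 1 <= CNV_MIN_LENGTH:
            continue
        out.append(
            CnvCall(
                contig=contig, start=start, end=end,
                cnv_type="loss" if svtype == "DEL" else "gain",
                filter_status=rec.FILTER or "PASS",
            )
        )
    return out
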