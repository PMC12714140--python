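"""Gene-level analytical-validity gating: coverage and CNV callability.

A gene can only be screened if variants in it are reliably detectable. Two
checks gate panel membership: sequencing coverage over the gene's exons
(mean, median, fraction of bases at >= 15x) and, for genes whose known
pathogenic variants are predominantly CNVs, the fraction of the gene that
falls inside homology regions the CNV caller excludes. A gene is removed
only when poor coverage affects essentially the whole gene (median and
mean < 30x and >= 95% of bases below 15x) or when CNV callability is
compromised in a CNV-predominant gene.

Depth tracks are consumed as bedGraph (the depth filters — mapping quality
> 10, base quality > 30, soft-clips removed — are a contract on how the
track was produced, not recomputed here). BED inputs are 0-based
half-open and converted to the package's 1-based inclusive convention at
this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import normalize_contig
from .knowledge import Thresholds


@dataclass
class CoverageSummary:
    """Per-exon and pooled depth metrics for one gene/transcript."""

    gene: str
    transcript: str
    mean_depth: float
    median_depth: float
    fraction_at_least: float  # fraction of bases with depth >= min_depth
    min_depth: int = 15
    per_exon: list = field(default_factory=list)  # [(interval, mean, median, frac)]

    @property
    def fraction_below(self) -> float:
        return 1.0 - self.fraction_at_least


@dataclass
class CallabilitySummary:
    gene: str
    fraction_excluded: float  # of the gene span inside homology-excluded regions


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive intervals (contig, start,
    end[, name]). This is the single 0-based -> 1-based conversion point."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name"][: _ncols(path)],
        dtype={0: str},
    )
    df["contig"] = df["contig"].map(lambda c: normalize_contig(c) or str(c))
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def _ncols(path: str | Path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(len(line.rstrip("\n").split("\t")), 4)
    return 3


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph depth track (contig, start, end, depth; 0-based
    half-open) into 1-based inclusive rows."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "depth"], dtype={0: str},
    )
    df["contig"] = df["contig"].map(lambda c: normalize_contig(c) or str(c))
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df["depth"] = df["depth"].astype(int)
    return df


def depths_over(
    track: pd.DataFrame, contig: str, intervals: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Per-base depths over a union of 1-based inclusive intervals.

    Positions not covered by any track row have depth 0.
    """
    rows = track[track["contig"] == contig]
    pieces = []
    for lo, hi in intervals:
        base = np.zeros(hi - lo + 1, dtype=np.int64)
        sel = rows[(rows["end"] >= lo) & (rows["start"] <= hi)]
        for r in sel.itertuples(index=False):
            a = max(r.start, lo) - lo
            b = min(r.end, hi) - lo
            base[a:b + 1] = r.depth
        pieces.append(base)
    return np.concatenate(pieces) if pieces else np.array([], dtype=np.int64)


def coverage_metrics(
    depth_track: pd.DataFrame,
    contig: str,
    exons: Sequence[tuple[int, int]],
    gene: str = "",
    transcript: str = "",
    min_depth: int = 15,
) -> CoverageSummary:
    """Exact mean/median/fraction->=min_depth per exon and pooled over all
    exon bases of a transcript."""
    if not exons:
        raise ValueError("coverage_metrics requires at least one exon interval")
    per_exon = []
    for exon in exons:
        d = depths_over(depth_track, contig, [exon])
        per_exon.append(
            (exon, float(d.mean()), float(np.median(d)), float((d >= min_depth).mean()))
        )
    pooled = depths_over(depth_track, contig, list(exons))
    return CoverageSummary(
        gene=gene,
        transcript=transcript,
        mean_depth=float(pooled.mean()),
        median_depth=float(np.median(pooled)),
        fraction_at_least=float((pooled >= min_depth).mean()),
        min_depth=min_depth,
        per_exon=per_exon,
    )


def cnv_callability(
    gene_span: tuple[int, int],
    excluded_regions: Sequence[tuple[int, int]],
    gene: str = "",
) -> CallabilitySummary:
    """Fraction of the gene span falling inside homology-excluded regions
    (regions the CNV caller cannot assess)."""
    lo, hi = gene_span
    length = hi - lo + 1
    if length <= 0:
        raise ValueError("gene span must have positive length")
    mask = np.zeros(length, dtype=bool)
    for a, b in excluded_regions:
        if b < lo or a > hi:
            continue
        mask[max(a, lo) - lo: min(b, hi) - lo + 1] = True
    return CallabilitySummary(gene=gene, fraction_excluded=float(mask.mean()))


def gene_exclusion_decision(
    cov: CoverageSummary,
    call: CallabilitySummary | None = None,
    cnv_predominant: bool = False,
    thresholds: Thresholds | None = None,
) -> tuple[str, str | None]:
    """Keep/exclude decision for one gene.

    Exclude iff poor coverage affects the entire gene (median < 30x AND
    mean < 30x AND >= 95% of bases below 15x), or the gene is
    CNV-predominant and its callability is compromised (fraction of the
    span in homology-excluded regions above the configured cut-off).
    Returns ("keep", None) or ("exclude", reason).
    """
    if thresholds is None:
        thresholds = Thresholds()
    t = thresholds
    if (
        cov.median_depth < t.coverage_mean_median_min
        and cov.mean_depth < t.coverage_mean_median_min
        and cov.fraction_below >= t.coverage_poor_fraction
    ):
        return "exclude", "coverage"
    if (
        cnv_predominant
        and call is not None
        and call.fraction_excluded > t.callability_compromised_fraction
    ):
        return "exclude", "callability"
    return "keep", None


def gene_qc_report(
    depth_track: pd.DataFrame,
    exons_by_gene: dict[str, tuple[str, str, list[tuple[int, int]]]],
    homology_regions: pd.DataFrame | None = None,
    cnv_predominant_genes: Sequence[str] = (),
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-gene QC table: coverage metrics, callability, and the
    keep/exclude decision with its reason.

    ``exons_by_gene`` maps gene -> (contig, transcript, exon intervals).
    """
    if thresholds is None:
        thresholds = Thresholds()
    rows = []
    for gene in sorted(exons_by_gene):
        contig, transcript, exons = exons_by_gene[gene]
        cov = coverage_metrics(
            depth_track, contig, exons, gene=gene, transcript=transcript,
            min_depth=thresholds.coverage_min_depth,
        )
        span = (min(a for a, _ in exons), max(b for _, b in exons))
        callab = None
        if homology_regions is not None:
            regs = homology_regions[homology_regions["contig"] == contig]
            callab = cnv_callability(
                span, [(r.start, r.end) for r in regs.itertuples(index=False)],
                gene=gene,
            )
        decision, reason = gene_exclusion_decision(
            cov, callab, gene in cnv_predominant_genes, thresholds
        )
        rows.append({
            "gene": gene,
            "transcript": transcript,
            "mean_depth": cov.mean_depth,
            "median_depth": cov.median_depth,
            "fraction_ge_min_depth": cov.fraction_at_least,
            "fraction_homology_excluded": (
                callab.fraction_excluded if callab is not None else ""
            ),
            "cnv_predominant": gene in cnv_predominant_genes,
            "decision": decision,
            "reason": reason or "",
        })
    return pd.DataFrame(rows)
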