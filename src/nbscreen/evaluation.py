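"""Specificity/sensitivity evaluation of the prioritization pipeline.

Specificity here is *sample-level*: the fraction of screened samples with
no prioritized variant at all. This is the quantity that determines
clinical-review workload in a screening programme, and it differs from
variant-level specificity — a single sample with three prioritized
variants costs one review, not three. Confidence intervals are Wilson
score intervals (well behaved for proportions near 1), and cohort
comparisons use the pooled two-proportion z-test with or without a
Yates-style continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

from .datamodel import NormalizedVariant
from .engine import PrioritizedCall, run_cohort
from .knowledge import Thresholds


@dataclass
class CohortResult:
    """Prioritization outcome over a cohort, with per-source breakdowns."""

    n_samples: int
    calls_by_sample: dict  # sample_id -> [PrioritizedCall]

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("cohort must contain samples")

    @property
    def flagged_samples(self) -> set:
        return {s for s, calls in self.calls_by_sample.items() if calls}

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_samples)

    def specificity(self) -> float:
        """Sample-level specificity, in percent."""
        return specificity(self.n_flagged, self.n_samples)

    def samples_by_source(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for sample_id, calls in self.calls_by_sample.items():
            for call in calls:
                for source in call.sources:
                    out.setdefault(source, set()).add(sample_id)
        return out

    def unique_variants_by_source(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for calls in self.calls_by_sample.values():
            for call in calls:
                for source in call.sources:
                    out.setdefault(source, set()).add(call.payload_key)
        return out

    def unique_variants(self) -> set:
        return {
            call.payload_key
            for calls in self.calls_by_sample.values()
            for call in calls
        }

    def samples_by_gene(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for sample_id, calls in self.calls_by_sample.items():
            for call in calls:
                if call.gene_condition is not None:
                    out.setdefault(call.gene_condition.gene_symbol, set()).add(sample_id)
        return out


def specificity(n_flagged: int, n_samples: int) -> float:
    """100 x (1 - flagged / total); sample-level, in percent."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return 100.0 * (1.0 - n_flagged / n_samples)


def wilson_ci(successes: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (fractions in [0,1]).

    Closed form: (p + z^2/2n +/- z*sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if z <= 0:
        raise ValueError("z must be positive")
    p = successes / n
    denom = 1.0 + z * z / n
    center = p + z * z / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return ((center - half) / denom, (center + half) / denom)


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> float:
    """Two-sided pooled z-test for equality of two binomial proportions.

    With ``continuity`` a Yates-style correction of (1/n1 + 1/n2)/2 is
    subtracted from |p1 - p2| before standardizing (matching R's
    ``prop.test`` chi-square up to the z<->chi2(1) identity).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie within sample sizes")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    diff = abs(p1 - p2)
    if continuity:
        diff = max(0.0, diff - (1 / n1 + 1 / n2) / 2)
    return 2 * float(norm.sf(diff / se))


def sensitivity(
    diagnostics_by_sample: Mapping[str, set],
    calls_by_sample: Mapping[str, Sequence[PrioritizedCall]],
    mask_sources: frozenset = frozenset(),
) -> float:
    """Percentage of case samples with >= 1 diagnostic variant prioritized.

    A diagnostic variant counts only if prioritized through at least one
    source outside ``mask_sources`` (a validation run masks the source the
    diagnostic variants themselves came from).
    """
    if not diagnostics_by_sample:
        raise ValueError("case cohort is empty")
    hits = 0
    for sample_id, diagnostic_keys in diagnostics_by_sample.items():
        if not diagnostic_keys:
            raise ValueError(f"sample {sample_id} lists no diagnostic variant")
        found = False
        for call in calls_by_sample.get(sample_id, []):
            if call.payload_key in diagnostic_keys and (call.sources - mask_sources):
                found = True
                break
        if found:
            hits += 1
    return 100.0 * hits / len(diagnostics_by_sample)


def cip_sweep(
    samples,
    panel,
    kb,
    exclusion,
    freqs,
    thresholds: Thresholds | None = None,
    scenarios: Sequence[str] = ("none", "p_and_no_b", "p_and_le1_b", "le1_b", "all"),
    companions=None,
) -> dict[str, CohortResult]:
    """Re-run the engine once per conflicting-interpretation scenario.

    The scenarios form a containment chain (each admits every variant the
    previous one admits), so flagged-sample counts are monotone
    non-decreasing along none -> p_and_no_b -> p_and_le1_b -> le1_b -> all.
    """
    if thresholds is None:
        thresholds = Thresholds()
    out = {}
    for scenario in scenarios:
        t = thresholds.replace(cip_mode=scenario)
        calls = run_cohort(samples, panel, kb, exclusion, freqs, t, companions)
        out[scenario] = CohortResult(n_samples=len(samples), calls_by_sample=calls)
    return out


# ---------------------------------------------------------------------------
# compound-het co-occurrence classification
# ---------------------------------------------------------------------------

PHASE_PREDICTIONS = ("same_haplotype", "different_haplotypes", "uncertain")


@dataclass
class CooccurrenceTable:
    """Local haplotype-prediction lookup for variant pairs (stand-in for a
    live population co-occurrence query); symmetric in pair order."""

    predictions: dict = field(default_factory=dict)  # frozenset({ka, kb}) -> prediction

    def add(self, key_a: tuple, key_b: tuple, prediction: str) -> None:
        if prediction not in PHASE_PREDICTIONS:
            raise ValueError(f"unknown phase prediction {prediction!r}")
        self.predictions[frozenset((key_a, key_b))] = prediction

    def lookup(self, key_a: tuple, key_b: tuple) -> str | None:
        return self.predictions.get(frozenset((key_a, key_b)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CooccurrenceTable":
        from .datamodel import normalize_variant

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        table = cls()
        for row in df.itertuples(index=False):
            a = normalize_variant(row.contig_a, int(row.pos_a), row.ref_a, row.alt_a).key
            b = normalize_variant(row.contig_b, int(row.pos_b), row.ref_b, row.alt_b).key
            table.add(a, b, row.prediction)
        return table


@dataclass
class CooccurrenceFractions:
    same: float | None
    different: float | None
    uncertain: float | None
    n_queryable: int
    n_unqueryable: int


def cooccurrence_classify(
    pairs: Sequence[tuple[tuple, tuple]], table: CooccurrenceTable
) -> CooccurrenceFractions:
    """Classify potential compound-het pairs by predicted phase.

    Fractions are over queryable pairs only; pairs absent from the table
    are counted separately. With zero queryable pairs the fractions are
    None (undefined), not zero.
    """
    counts = {p: 0 for p in PHASE_PREDICTIONS}
    unqueryable = 0
    for key_a, key_b in pairs:
        pred = table.lookup(key_a, key_b)
        if pred is None:
            unqueryable += 1
        else:
            counts[pred] += 1
    n_query = sum(counts.values())
    if n_query == 0:
        return CooccurrenceFractions(None, None, None, 0, unqueryable)
    return CooccurrenceFractions(
        same=counts["same_haplotype"] / n_query,
        different=counts["different_haplotypes"] / n_query,
        uncertain=counts["uncertain"] / n_query,
        n_queryable=n_query,
        n_unqueryable=unqueryable,
    )


def comphet_pairs(calls_by_sample: Mapping[str, Sequence[PrioritizedCall]]) -> list:
    """Extract unique (sample, pair) compound-het variant pairs from a run."""
    out = []
    seen = set()
    for sample_id, calls in calls_by_sample.items():
        for call in calls:
            if not call.zygosity_rationale.startswith("biallelic_comphet"):
                continue
            for partner in call.comphet_partners:
                pair_id = (sample_id, frozenset((call.payload_key, tuple(partner))))
                if pair_id not in seen:
                    seen.add(pair_id)
                    out.append((call.payload_key, tuple(partner)))
    return out


# ---------------------------------------------------------------------------
# Table-style evaluation report
# ---------------------------------------------------------------------------

def evaluation_table(result: CohortResult, z: float = 1.96) -> pd.DataFrame:
    """Per-source and overall evaluation rows: unique variant count,
    flagged-sample count, sample-level specificity, and Wilson CI (percent)."""
    rows = []
    by_source_samples = result.samples_by_source()
    by_source_variants = result.unique_variants_by_source()
    for source in sorted(by_source_samples):
        rows.append(_eval_row(
            source,
            len(by_source_variants.get(source, ())),
            len(by_source_samples[source]),
            result.n_samples, z,
        ))
    rows.append(_eval_row(
        "all", len(result.unique_variants()), result.n_flagged, result.n_samples, z
    ))
    return pd.DataFrame(rows)


def _eval_row(source: str, n_variants: int, n_flagged: int, n: int, z: float) -> dict:
    lo, hi = wilson_ci(n - n_flagged, n, z)
    return {
        "source": source,
        "unique_variants": n_variants,
        "flagged_samples": n_flagged,
        "specificity_pct": round(specificity(n_flagged, n), 2),
        "ci_low_pct": round(100 * lo, 2),
        "ci_high_pct": round(100 * hi, 2),
    }
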