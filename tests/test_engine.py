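"""Rule-engine behaviour: filters, MOI gating, source rules, CNV rules."""

import numpy as np
import pytest

from nbscreen.datamodel import (
    CnvCall,
    GenotypeCall,
    NormalizedVariant,
    TranscriptAnnotation,
)
from nbscreen.engine import (
    SampleData,
    SmnResult,
    _Candidate,
    cnv_reference_frequency,
    companion_flags,
    moi_gate,
    prioritize_cnv,
    prioritize_plof_small,
    prioritize_reported,
    reciprocal_overlap,
    run_cohort,
    run_sample,
    select_transcript,
    smn1_rule,
    universal_filter,
)
from nbscreen.knowledge import (
    ClassificationRecord,
    ExclusionEntry,
    ExclusionList,
    FrequencyReference,
    GeneConditionPair,
    KnowledgeBase,
    Thresholds,
)

T = Thresholds()
EMPTY_EXCL = ExclusionList()


def pair(gene="G1", moi="monoallelic", lof=False, incl_only=False,
         contig="1", start=1000, end=9000, exons=()):
    return GeneConditionPair(gene, f"cond_{gene}", moi, lof, incl_only,
                             contig, start, end, f"tx_{gene}", exons)


def variant(pos=5000, ref="A", alt="T", contig="1", filt="PASS", anns=()):
    v = NormalizedVariant(contig, pos, ref, alt, filter_status=filt)
    v.annotations = list(anns)
    return v


def cand(v, zygosity="het", ps=None, hap=None):
    return _Candidate(payload=v, zygosity=zygosity, phase_set_id=ps,
                      haplotype_index=hap, sources={"clinvar_like"},
                      position=v.pos)


def p_record(v, source="clinvar_like", gene="G1"):
    return ClassificationRecord(source, "P", gene=gene, variant_key=v.key)


class TestUniversalFilter:
    def test_pass_variant_passes(self):
        assert universal_filter(variant(), EMPTY_EXCL) == (True, None)

    def test_non_pass_fails_even_with_evidence(self):
        ok, reason = universal_filter(variant(filt="LowQual"), EMPTY_EXCL)
        assert (ok, reason) == (False, "filter_status")

    def test_excluded_variant_fails(self):
        v = variant()
        excl = ExclusionList([ExclusionEntry(v.key, "artefact")])
        assert universal_filter(v, excl) == (False, "excluded")


class TestMoiGate:
    def test_monoallelic_het_passes_alone(self):
        out = moi_gate([cand(variant())], "monoallelic")
        assert [r for _, r in out] == ["monoallelic_het"]

    def test_biallelic_single_het_blocked(self):
        assert moi_gate([cand(variant())], "biallelic") == []

    def test_biallelic_hom_passes_alone(self):
        out = moi_gate([cand(variant(), "hom_alt")], "biallelic")
        assert [r for _, r in out] == ["biallelic_hom"]

    def test_cis_pair_within_phasing_window_collapses(self):
        a = cand(variant(5000), ps="1:5000", hap=1)
        b = cand(variant(5080, "G", "C"), ps="1:5000", hap=1)
        assert moi_gate([a, b], "biallelic", 150) == []

    def test_trans_phased_pair_passes_as_comphet(self):
        a = cand(variant(5000), ps="1:5000", hap=0)
        b = cand(variant(5080, "G", "C"), ps="1:5000", hap=1)
        out = moi_gate([a, b], "biallelic", 150)
        assert [r for _, r in out] == ["biallelic_comphet_trans"]

    def test_unphased_pair_passes_as_comphet(self):
        a = cand(variant(5000), ps="1:5000", hap=1)
        b = cand(variant(7000, "G", "C"), ps="1:7000", hap=1)
        out = moi_gate([a, b], "biallelic", 150)
        assert [r for _, r in out] == ["biallelic_comphet_unphased"]
        assert len(out[0][0]) == 2

    def test_same_phase_far_apart_treated_as_unphased(self):
        # phase sets agree but the pair is outside the trusted phasing range
        a = cand(variant(5000), ps="1:5000", hap=1)
        b = cand(variant(5400, "G", "C"), ps="1:5000", hap=1)
        out = moi_gate([a, b], "biallelic", 150)
        assert [r for _, r in out] == ["biallelic_comphet_unphased"]

    def test_cis_pair_plus_third_het_is_comphet(self):
        a = cand(variant(5000), ps="1:5000", hap=1)
        b = cand(variant(5080, "G", "C"), ps="1:5000", hap=1)
        c = cand(variant(8000, "T", "G"))
        out = moi_gate([a, b, c], "biallelic", 150)
        assert [r for _, r in out] == ["biallelic_comphet_unphased"]
        assert len(out[0][0]) == 3

    def test_x_linked_hemizygote_passes(self):
        out = moi_gate([cand(variant(contig="X"), "hemi")], "x_linked")
        assert [r for _, r in out] == ["hemizygous"]

    def test_x_linked_single_het_blocked(self):
        assert moi_gate([cand(variant(contig="X"))], "x_linked") == []


class TestPrioritizeReported:
    def _freqs(self, af=None, key=None):
        f = FrequencyReference()
        if af is not None:
            f.internal[key] = af
        return f

    def test_clinvar_pathogenic_rare_fires(self):
        v = variant()
        kb = KnowledgeBase([p_record(v)])
        got = prioritize_reported(v, pair(), kb, self._freqs(0.001, v.key), T)
        assert got == {"clinvar_like"}

    def test_common_variant_vetoed_for_every_source(self):
        v = variant()
        kb = KnowledgeBase([p_record(v), p_record(v, "cva_like"),
                            p_record(v, "curated_commercial")])
        assert prioritize_reported(v, pair(), kb, self._freqs(0.07, v.key), T) == set()

    def test_absent_internal_af_counts_as_rare(self):
        v = variant()
        kb = KnowledgeBase([p_record(v)])
        assert prioritize_reported(v, pair(), kb, FrequencyReference(), T) \
            == {"clinvar_like"}

    def test_mnv_uses_min_decomposed_af(self):
        v = variant(5000, "AG", "TC")
        kb = KnowledgeBase([p_record(v, "curated_commercial")])
        f = FrequencyReference()
        f.internal[("1", 5000, "A", "T")] = 0.2
        f.internal[("1", 5001, "G", "C")] = 0.01
        assert prioritize_reported(v, pair(), kb, f, T) == {"curated_commercial"}
        f.internal[("1", 5001, "G", "C")] = 0.2
        assert prioritize_reported(v, pair(), kb, f, T) == set()

    def test_inclusion_list_only_gene_ignores_other_sources(self):
        v = variant()
        kb = KnowledgeBase([p_record(v), p_record(v, "cva_like")])
        assert prioritize_reported(v, pair(incl_only=True), kb,
                                   FrequencyReference(), T) == set()
        kb.add(ClassificationRecord("internal_inclusion", "P", gene="G1",
                                    variant_key=v.key,
                                    evidence_ids=("PMID:1",)))
        assert prioritize_reported(v, pair(incl_only=True), kb,
                                   FrequencyReference(), T) == {"internal_inclusion"}

    def test_multi_source_provenance(self):
        v = variant()
        kb = KnowledgeBase([p_record(v), p_record(v, "cva_like"),
                            p_record(v, "curated_commercial")])
        got = prioritize_reported(v, pair(), kb, FrequencyReference(), T)
        assert got == {"clinvar_like", "cva_like", "curated_commercial"}


class TestSelectTranscript:
    def ann(self, tx, flags, cds=None):
        return TranscriptAnnotation("G1", tx, ("stop_gained",), "high",
                                    transcript_flags=frozenset(flags),
                                    cds_length=cds)

    def test_mane_select_preferred(self):
        got = select_transcript(
            [self.ann("tx2", ["predefined_canonical"]),
             self.ann("tx1", ["mane_select"])], pair())
        assert got.transcript_id == "tx1"

    def test_fallback_to_predefined(self):
        got = select_transcript([self.ann("tx3", ["predefined_canonical"])], pair())
        assert got.transcript_id == "tx3"

    def test_no_flagged_transcript_gives_none(self):
        assert select_transcript([self.ann("tx4", [])], pair()) is None

    def test_tie_break_longest_cds_then_id(self):
        got = select_transcript(
            [self.ann("tx_b", ["mane_select"], cds=900),
             self.ann("tx_a", ["mane_select"], cds=1200)], pair())
        assert got.transcript_id == "tx_a"
        got = select_transcript(
            [self.ann("tx_b", ["mane_select"], cds=900),
             self.ann("tx_a", ["mane_select"], cds=900)], pair())
        assert got.transcript_id == "tx_a"


class TestPlofSmall:
    def _v(self, impact="high", cons="stop_gained"):
        return variant(anns=[TranscriptAnnotation(
            "G1", "tx1", (cons,), impact,
            transcript_flags=frozenset({"mane_select"}))])

    def test_high_impact_rare_lof_gene_fires(self):
        assert prioritize_plof_small(self._v(), pair(lof=True),
                                     FrequencyReference(), T)

    def test_non_lof_gene_never_fires(self):
        assert not prioritize_plof_small(self._v(), pair(lof=False),
                                         FrequencyReference(), T)

    def test_missense_never_fires(self):
        v = self._v(impact="moderate", cons="missense_variant")
        assert not prioritize_plof_small(v, pair(lof=True), FrequencyReference(), T)

    def test_population_af_above_threshold_vetoes(self):
        f = FrequencyReference()
        v = self._v()
        f.population[v.key] = {"global": 2e-4}  # above the 1e-4 monoallelic cap
        assert not prioritize_plof_small(v, pair(lof=True), f, T)
        f.population[v.key] = {"global": 5e-5}
        assert prioritize_plof_small(v, pair(lof=True), f, T)

    def test_biallelic_threshold_is_looser(self):
        f = FrequencyReference()
        v = self._v()
        f.population[v.key] = {"global": 2e-3}
        assert not prioritize_plof_small(v, pair(moi="monoallelic", lof=True), f, T)
        assert prioritize_plof_small(v, pair(moi="biallelic", lof=True), f, T)


class TestReciprocalOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        ((100, 199), (100, 199), 1.0),
        ((100, 199), (300, 399), 0.0),
        ((100, 199), (150, 249), 0.5),
    ])
    def test_worked_examples(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)

    def test_matches_per_base_counting_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            a = sorted(rng.integers(1, 500, size=2))
            b = sorted(rng.integers(1, 500, size=2))
            a = (int(a[0]), int(a[1]))
            b = (int(b[0]), int(b[1]))
            bases_a = set(range(a[0], a[1] + 1))
            bases_b = set(range(b[0], b[1] + 1))
            shared = len(bases_a & bases_b)
            expected = min(shared / len(bases_a), shared / len(bases_b))
            assert reciprocal_overlap(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = tuple(sorted(int(x) for x in rng.integers(1, 300, 2)))
            b = tuple(sorted(int(x) for x in rng.integers(1, 300, 2)))
            assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)


class TestCnvRules:
    GENE = pair("G1", lof=True, start=30_000, end=60_000,
                exons=((32_000, 34_000), (55_000, 57_000)))

    def ref_entry(self, start, end, typ, freq):
        return (CnvCall("1", start, end, typ), freq)

    def test_reference_frequency_scan(self):
        cnv = CnvCall("1", 10_000, 20_000, "loss")
        assert cnv_reference_frequency(cnv, []) == 0.0
        refs = [self.ref_entry(10_500, 20_500, "loss", 0.004),
                self.ref_entry(10_000, 20_000, "gain", 0.9)]
        assert cnv_reference_frequency(cnv, refs, 0.8) == 0.004

    def test_opposite_type_reference_ignored(self):
        cnv = CnvCall("1", 10_000, 20_000, "gain")
        refs = [self.ref_entry(10_000, 20_000, "loss", 0.9)]
        assert cnv_reference_frequency(cnv, refs, 0.8) == 0.0

    def test_rare_loss_over_coding_region_fires(self):
        cnv = CnvCall("1", 33_000, 53_000, "loss")
        assert prioritize_cnv(cnv, self.GENE, FrequencyReference(), T)

    def test_flank_reaches_coding_region(self):
        # ends 1.5 kb short of the first exon: the 2 kb flank bridges it
        cnv = CnvCall("1", 25_000, 30_500, "loss")
        assert prioritize_cnv(cnv, self.GENE, FrequencyReference(), T)
        far = CnvCall("1", 20_000, 29_000, "loss")
        assert not prioritize_cnv(far, self.GENE, FrequencyReference(), T)

    def test_gain_with_breakpoint_outside_transcript_blocked(self):
        inside = CnvCall("1", 31_000, 58_000, "gain")
        assert prioritize_cnv(inside, self.GENE, FrequencyReference(), T)
        spanning = CnvCall("1", 31_000, 65_000, "gain")
        assert not prioritize_cnv(spanning, self.GENE, FrequencyReference(), T)

    def test_common_loss_blocked_by_moi_threshold(self):
        cnv = CnvCall("1", 33_000, 53_000, "loss")
        f = FrequencyReference(cnv_reference=[self.ref_entry(33_000, 53_000,
                                                             "loss", 0.002)])
        assert not prioritize_cnv(cnv, self.GENE, f, T)  # 0.002 >= 0.001 dominant
        rec_gene = pair("G1", moi="biallelic", lof=True, start=30_000,
                        end=60_000, exons=((32_000, 34_000),))
        assert prioritize_cnv(cnv, rec_gene, f, T)  # < 0.005 recessive

    def test_non_lof_gene_blocked(self):
        cnv = CnvCall("1", 33_000, 53_000, "loss")
        assert not prioritize_cnv(cnv, pair("G1", lof=False, start=30_000,
                                            end=60_000), FrequencyReference(), T)


class TestSmnRule:
    @pytest.mark.parametrize("cn,fires", [(0, True), (1, False), (2, False)])
    def test_fires_only_on_zero_copies(self, cn, fires):
        assert smn1_rule(SmnResult("s1", cn)) is fires

    def test_negative_copy_number_rejected(self):
        with pytest.raises(ValueError):
            SmnResult("s1", -1)


class TestCompanionFlags:
    TRIGGER = ("3", 15_000, "G", "A")
    COMPANION = ("3", 17_000, "G", "C")
    TABLE = {TRIGGER: [COMPANION]}

    def test_reports_companion_genotype(self):
        genos = {self.COMPANION: GenotypeCall("s1", self.COMPANION, "het")}
        got = companion_flags(self.TRIGGER, self.TABLE, genos)
        assert got == [{"companion": list(self.COMPANION), "genotype": "het"}]

    def test_absent_companion_reported_as_absent(self):
        got = companion_flags(self.TRIGGER, self.TABLE, {})
        assert got == [{"companion": list(self.COMPANION), "genotype": "absent"}]

    def test_no_companions_configured(self):
        assert companion_flags(("1", 1, "A", "T"), self.TABLE, {}) == []
        assert companion_flags(self.TRIGGER, None, {}) == []


class TestRunSample:
    def _setup(self, moi="monoallelic"):
        g = pair("G1", moi=moi)
        v = variant()
        kb = KnowledgeBase([p_record(v)])
        geno = GenotypeCall("s1", v.key, "het")
        sample = SampleData("s1", small_variants=[(v, geno)])
        return sample, [g], kb

    def test_het_pathogenic_in_dominant_gene_prioritized(self):
        sample, panel, kb = self._setup("monoallelic")
        calls = run_sample(sample, panel, kb, EMPTY_EXCL, FrequencyReference())
        assert len(calls) == 1
        assert calls[0].sources == {"clinvar_like"}
        assert calls[0].zygosity_rationale == "monoallelic_het"

    def test_het_pathogenic_in_recessive_gene_not_prioritized(self):
        sample, panel, kb = self._setup("biallelic")
        assert run_sample(sample, panel, kb, EMPTY_EXCL, FrequencyReference()) == []

    def test_exclusion_beats_every_source(self):
        sample, panel, kb = self._setup("monoallelic")
        v = sample.small_variants[0][0]
        excl = ExclusionList([ExclusionEntry(v.key, "artefact")])
        assert run_sample(sample, panel, kb, excl, FrequencyReference()) == []

    def test_exclusion_is_monotone(self):
        """Adding exclusion entries never increases the number of calls."""
        samples, panel, kb, excl_entries = self._multi_variant_setup()
        freqs = FrequencyReference()
        counts = []
        for i in range(len(excl_entries) + 1):
            excl = ExclusionList(excl_entries[:i])
            calls = run_sample(samples, panel, kb, excl, freqs)
            counts.append(len(calls))
        assert counts == sorted(counts, reverse=True)

    def _multi_variant_setup(self):
        g = pair("G1")
        vs = [variant(3000 + 100 * i, "A", "T") for i in range(4)]
        kb = KnowledgeBase([p_record(v) for v in vs])
        sample = SampleData("s1", small_variants=[
            (v, GenotypeCall("s1", v.key, "het")) for v in vs
        ])
        entries = [ExclusionEntry(v.key, "artefact") for v in vs]
        return sample, [g], kb, entries

    def test_smn_zero_copies_prioritizes_case(self):
        sample = SampleData("s1", smn=SmnResult("s1", 0))
        calls = run_sample(sample, [], KnowledgeBase(), EMPTY_EXCL,
                           FrequencyReference())
        assert len(calls) == 1 and calls[0].sources == {"smn1"}
        sample2 = SampleData("s2", smn=SmnResult("s2", 2))
        assert run_sample(sample2, [], KnowledgeBase(), EMPTY_EXCL,
                          FrequencyReference()) == []

    def test_cnv_loss_pairs_with_het_snv_in_recessive_gene(self):
        g = pair("G1", moi="biallelic", lof=True, start=30_000, end=60_000)
        v = variant(35_000)
        kb = KnowledgeBase([p_record(v)])
        cnv = CnvCall("1", 40_000, 55_000, "loss")
        sample = SampleData("s1",
                            small_variants=[(v, GenotypeCall("s1", v.key, "het"))],
                            cnvs=[cnv])
        calls = run_sample(sample, [g], kb, EMPTY_EXCL, FrequencyReference())
        assert {c.zygosity_rationale for c in calls} == {"biallelic_comphet_unphased"}
        assert len(calls) == 2
        # behind the config flag the pairing is disabled
        t_off = T.replace(cnv_comphet_with_snv=False)
        calls_off = run_sample(sample, [g], kb, EMPTY_EXCL, FrequencyReference(),
                               t_off)
        assert calls_off == []

    def test_hom_cnv_loss_alone_satisfies_recessive_gene(self):
        g = pair("G1", moi="biallelic", lof=True, start=30_000, end=60_000)
        cnv = CnvCall("1", 40_000, 55_000, "loss", copy_number=0)
        sample = SampleData("s1", cnvs=[cnv])
        calls = run_sample(sample, [g], KnowledgeBase(), EMPTY_EXCL,
                           FrequencyReference())
        assert [c.zygosity_rationale for c in calls] == ["biallelic_hom"]


class TestCohortDeterminism:
    def test_identical_inputs_identical_reports(self, bundle):
        from nbscreen.engine import calls_to_frame
        samples, panel, kb, exclusion, freqs, companions, _ = bundle
        a = run_cohort(samples, panel, kb, exclusion, freqs, companions=companions)
        b = run_cohort(samples, panel, kb, exclusion, freqs, companions=companions)
        assert calls_to_frame(a).to_csv() == calls_to_frame(b).to_csv()
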