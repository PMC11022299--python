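"""Triage cascade, dedup, per-patient rollup and Venn overlap counts."""

import itertools
import random

import pytest

from repurpose import synth
from repurpose.errors import AnalysisError
from repurpose.tables import (
    EvidenceEntry,
    EvidenceIndex,
    FDALabelEntry,
    PatientReport,
    ProbeRecord,
    VariantCall,
    assign_ranks,
)
from repurpose.triage import (
    ACTIONABLE_CATEGORIES,
    EventCategory,
    TierOnePolicy,
    categorize_event,
    find_candidate_drugs,
    overlap_summary,
    triage_cohort,
)
from repurpose.validation import ThresholdPolicy
from repurpose.variants import classify_cohort


def _evidence(**genes):
    return EvidenceIndex.from_entries(
        EvidenceEntry(gene=g, has_trial_evidence=t, known_off_label=o)
        for g, (t, o) in genes.items()
    )


class TestCategorize:
    def test_tier1_wins(self):
        cat = categorize_event(
            "KRAS", [("d", 0.5)], TierOnePolicy(), _evidence(KRAS=(True, True))
        )
        assert cat is EventCategory.tier1_excluded

    def test_trial_evidence_preempts_off_label(self):
        cat = categorize_event(
            "AURKA", [("d", 0.5)], TierOnePolicy(), _evidence(AURKA=(True, True))
        )
        assert cat is EventCategory.trial_level

    def test_off_label_before_novel(self):
        cat = categorize_event(
            "AURKA", [("d", 0.5)], TierOnePolicy(), _evidence(AURKA=(False, True))
        )
        assert cat is EventCategory.off_label

    def test_no_evidence_is_novel(self):
        cat = categorize_event(
            "AURKA", [("d", 0.5)], TierOnePolicy(), _evidence()
        )
        assert cat is EventCategory.novel

    def test_empty_candidates_rejected(self):
        with pytest.raises(AnalysisError):
            categorize_event("AURKA", [], TierOnePolicy(), _evidence())


class TestFindCandidates:
    def test_descending_score_order(self):
        probes = assign_ranks(
            [
                ProbeRecord(compound_id=c, target_gene="AURKA", global_score=s)
                for c, s in [("a", 0.3), ("b", 0.7), ("c", 0.5), ("d", 0.1)]
            ]
        )
        got = find_candidate_drugs("AURKA", probes, {"a", "b", "c", "d"}, ThresholdPolicy())
        assert got == [("b", 0.7), ("c", 0.5), ("a", 0.3)]

    def test_no_passing_drug_empty(self):
        probes = assign_ranks(
            [ProbeRecord(compound_id="a", target_gene="AURKA", global_score=0.1)]
        )
        assert find_candidate_drugs("AURKA", probes, {"a"}, ThresholdPolicy()) == []


def _mini_cohort():
    """Two patients sharing a CCND1 amplification; one KRAS hotspot."""
    reports = [
        PatientReport(
            patient_id="p1",
            variants=[
                VariantCall(patient_id="p1", gene="CCND1", mutation_type="amplification"),
                VariantCall(
                    patient_id="p1", gene="KRAS", mutation_type="nsSNV",
                    protein_change="G12D", vaf=0.4,
                ),
            ],
        ),
        PatientReport(
            patient_id="p2",
            variants=[
                VariantCall(patient_id="p2", gene="CCND1", mutation_type="amplification"),
            ],
        ),
    ]
    probes = assign_ranks(
        [
            ProbeRecord(compound_id="dA", target_gene="CCND1", global_score=0.6),
            ProbeRecord(compound_id="dB", target_gene="KRAS", global_score=0.5),
            ProbeRecord(compound_id="dC", target_gene="CCND1", global_score=0.1),
        ]
    )
    labels = [
        FDALabelEntry(drug_id="dA", target_gene="OTHER1"),
        FDALabelEntry(drug_id="dB", target_gene="OTHER2"),
        FDALabelEntry(drug_id="dC", target_gene="OTHER3"),
    ]
    return reports, probes, labels


class TestTriageCohort:
    def test_shared_event_dedups(self):
        reports, probes, labels = _mini_cohort()
        from repurpose.variants import KnowledgeBase

        annotations = classify_cohort(reports, KnowledgeBase())
        result = triage_cohort(
            reports, annotations, probes, labels, _evidence(CCND1=(False, True))
        )
        ccnd1 = [e for e in result.events if e.gene == "CCND1"]
        assert len(ccnd1) == 2
        assert sum(1 for e in result.unique_events if e.gene == "CCND1") == 1
        # KRAS is Tier I: present but excluded from downstream categories
        kras = [e for e in result.events if e.gene == "KRAS"]
        assert [e.category for e in kras] == [EventCategory.tier1_excluded]

    def test_dedup_idempotent_and_bounded(self):
        reports, probes, labels = _mini_cohort()
        from repurpose.triage import _dedup
        from repurpose.variants import KnowledgeBase

        annotations = classify_cohort(reports, KnowledgeBase())
        result = triage_cohort(reports, annotations, probes, labels, _evidence())
        once = _dedup(result.events, "gene_type")
        assert _dedup(once, "gene_type") == once
        assert len(once) <= len(result.events)

    def test_tier1_only_cohort_has_no_actionable_events(self):
        reports, probes, labels = _mini_cohort()
        from repurpose.variants import KnowledgeBase

        annotations = classify_cohort(reports, KnowledgeBase())
        tier1 = TierOnePolicy(genes=frozenset({"KRAS", "CCND1"}))
        result = triage_cohort(
            reports, annotations, probes, labels, _evidence(), tier1=tier1
        )
        assert result.patients_with_actionable == set()
        assert all(e.category is EventCategory.tier1_excluded for e in result.events)

    def test_partition_and_per_patient_recount_on_synthetic_cohort(self, small_cfg):
        probes, _ = synth.gen_probe_table(small_cfg)
        labels = synth.gen_fda_labels(small_cfg)
        reports, _ = synth.gen_patient_reports(small_cfg)
        kb = synth.gen_knowledge_base(small_cfg)
        evidence = synth.gen_evidence_index(small_cfg)
        annotations = classify_cohort(reports, kb)
        tier1 = TierOnePolicy(genes=frozenset({"GENE001"}))
        result = triage_cohort(
            reports, annotations, probes, labels, evidence, tier1=tier1
        )
        # partition: each event in exactly one category
        for e in result.events:
            assert e.category in EventCategory
        # tier-one dominance
        assert all(
            e.category is EventCategory.tier1_excluded
            for e in result.events
            if e.gene == "GENE001"
        )
        # independent recount oracle over the raw events list
        recount = {
            e.patient_id for e in result.events if e.category in ACTIONABLE_CATEGORIES
        }
        assert result.patients_with_actionable == recount
        assert result.actionable_patient_fraction == len(recount) / len(reports)

    def test_enlarging_trial_flags_never_increases_novel(self, small_cfg):
        probes, _ = synth.gen_probe_table(small_cfg)
        labels = synth.gen_fda_labels(small_cfg)
        reports, _ = synth.gen_patient_reports(small_cfg)
        kb = synth.gen_knowledge_base(small_cfg)
        annotations = classify_cohort(reports, kb)

        def novel_count(evidence):
            res = triage_cohort(reports, annotations, probes, labels, evidence)
            return res.category_counts()["novel"]

        none_flagged = EvidenceIndex.from_entries(
            EvidenceEntry(gene=g) for g in small_cfg.gene_names
        )
        all_flagged = EvidenceIndex.from_entries(
            EvidenceEntry(gene=g, has_trial_evidence=True)
            for g in small_cfg.gene_names
        )
        assert novel_count(all_flagged) <= novel_count(none_flagged)
        assert novel_count(all_flagged) == 0


class TestOverlapSummary:
    def test_identical_sets(self):
        out = overlap_summary({"A": {1, 2}, "B": {1, 2}})
        assert out[frozenset({"A", "B"})] == 2
        assert out[frozenset({"A"})] == 0 and out[frozenset({"B"})] == 0

    def test_disjoint_sets(self):
        out = overlap_summary({"A": {1}, "B": {2}})
        assert out[frozenset({"A", "B"})] == 0
        assert out[frozenset({"A"})] == 1 and out[frozenset({"B"})] == 1

    def test_matches_membership_pattern_oracle(self):
        rnd = random.Random(9)
        for _ in range(20):
            sets = {
                name: set(rnd.sample(range(10), rnd.randint(0, 10)))
                for name in ("A", "B", "C")
            }
            out = overlap_summary(sets)
            # oracle: enumerate all 2^3 membership patterns per element
            expected = {k: 0 for k in out}
            for x in set().union(*sets.values()):
                pattern = frozenset(n for n in sets if x in sets[n])
                expected[pattern] += 1
            assert out == expected
            assert sum(out.values()) == len(set().union(*sets.values()))

    def test_single_source_rejected(self):
        with pytest.raises(AnalysisError):
            overlap_summary({"A": {1}})
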