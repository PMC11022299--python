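"""Gold-standard validation: universe, thresholding, confusion matrices."""

import random

import pytest

from repurpose import synth
from repurpose.errors import AnalysisError, ConfigError
from repurpose.tables import FDALabelEntry, ProbeRecord, assign_ranks
from repurpose.validation import (
    Comparator,
    ConfusionMatrix,
    ThresholdPolicy,
    build_drug_universe,
    classification_metrics,
    confusion_matrix_for_gene,
    eligible_genes,
    predicted_drugs_for_gene,
    round_half_up,
    validate_gold_standard,
)


def _probes(rows):
    return assign_ranks(
        [
            ProbeRecord(compound_id=c, target_gene=g, global_score=s)
            for c, g, s in rows
        ]
    )


class TestUniverse:
    def test_intersection(self):
        probes = _probes([("b", "G", 0.5), ("c", "G", 0.5), ("d", "G", 0.5)])
        assert build_drug_universe(probes, ["a", "b", "c"]) == {"b", "c"}

    def test_disjoint_is_error(self):
        probes = _probes([("x", "G", 0.5)])
        with pytest.raises(AnalysisError, match="no drug"):
            build_drug_universe(probes, ["a", "b"])


class TestPrediction:
    def test_strict_threshold_boundary(self):
        probes = _probes([("a", "G", 0.3), ("b", "G", 0.25), ("c", "G", 0.1)])
        universe = {"a", "b", "c"}
        strict = ThresholdPolicy(tau=0.25, comparator=Comparator.greater)
        assert predicted_drugs_for_gene("G", probes, universe, strict) == {"a"}
        loose = ThresholdPolicy(tau=0.25, comparator=Comparator.greater_or_equal)
        assert predicted_drugs_for_gene("G", probes, universe, loose) == {"a", "b"}

    def test_absent_gene_is_empty(self):
        probes = _probes([("a", "G", 0.5)])
        assert predicted_drugs_for_gene("X", probes, {"a"}, ThresholdPolicy()) == set()

    def test_matches_exhaustive_scan_oracle(self):
        rnd = random.Random(42)
        probes = _probes(
            [(f"d{i}", f"G{i % 5}", round(rnd.random(), 3)) for i in range(100)]
        )
        universe = {f"d{i}" for i in range(0, 100, 2)}
        policy = ThresholdPolicy(tau=0.25)
        for gene in {r.target_gene for r in probes}:
            expected = set()
            for r in probes:  # brute force over all rows
                if (
                    r.target_gene == gene
                    and r.compound_id in universe
                    and r.global_score > 0.25
                ):
                    expected.add(r.compound_id)
            assert predicted_drugs_for_gene(gene, probes, universe, policy) == expected


class TestEligibleGenes:
    def _labels(self, pairs):
        return [FDALabelEntry(drug_id=d, target_gene=g) for d, g in pairs]

    def test_single_therapy_gene_excluded_by_default(self):
        labels = self._labels([("a", "G1"), ("b", "G2"), ("c", "G2")])
        assert eligible_genes(labels) == {"G2"}

    def test_min_therapies_one_keeps_all(self):
        labels = self._labels([("a", "G1"), ("b", "G2")])
        assert eligible_genes(labels, min_therapies=1) == {"G1", "G2"}

    def test_invalid_min_therapies(self):
        with pytest.raises(ConfigError):
            eligible_genes([], min_therapies=0)


class TestConfusionMatrix:
    def test_known_counts(self):
        universe = {f"d{i}" for i in range(749)}
        truth = {"d0", "d1", "d2"}
        predicted = truth | {"d3", "d4", "d5", "d6", "d7"}
        cm = confusion_matrix_for_gene("G", predicted, truth, universe)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (3, 5, 741, 0)
        assert cm.total == 749

    def test_perfect_classifier(self):
        universe = {"a", "b", "c", "d"}
        cm = confusion_matrix_for_gene("G", {"a", "b"}, {"a", "b"}, universe)
        assert cm.fp == 0 and cm.fn == 0

    def test_truth_outside_universe_rejected(self):
        with pytest.raises(AnalysisError, match="absent from universe"):
            confusion_matrix_for_gene("G", set(), {"zzz"}, {"a"})

    def test_matches_per_drug_labelling_oracle(self):
        rnd = random.Random(1)
        universe = {f"d{i}" for i in range(20)}
        for _ in range(25):
            truth = set(rnd.sample(sorted(universe), rnd.randint(0, 8)))
            predicted = set(rnd.sample(sorted(universe), rnd.randint(0, 12)))
            cm = confusion_matrix_for_gene("G", predicted, truth, universe)
            # oracle: classify every drug independently
            tp = fp = tn = fn = 0
            for d in universe:
                if d in predicted and d in truth:
                    tp += 1
                elif d in predicted:
                    fp += 1
                elif d in truth:
                    fn += 1
                else:
                    tn += 1
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            # (tp, fp, tn, fn) -> (sensitivity, specificity, precision) at 2dp
            ((3, 5, 741, 0), (1.0, 0.99, 0.38)),
            ((3, 11, 734, 1), (0.75, 0.99, 0.21)),
            ((2, 14, 733, 0), (1.0, 0.98, 0.13)),  # half-up: 2/16 = 0.125 -> 0.13
        ],
    )
    def test_metric_triples(self, cells, expected):
        m = classification_metrics(ConfusionMatrix("G", *cells))
        got = tuple(
            round_half_up(v) for v in (m.sensitivity, m.specificity, m.precision)
        )
        assert got == expected

    def test_degenerate_undefined_flags(self):
        m = classification_metrics(ConfusionMatrix("G", 0, 0, 10, 0))
        assert m.precision is None and m.sensitivity is None
        assert m.specificity == 1.0


class TestValidateGoldStandard:
    def test_probe_equals_gold_standard(self):
        labels = [
            FDALabelEntry(drug_id=d, target_gene=g)
            for d, g in [("a", "G1"), ("b", "G1"), ("c", "G2"), ("d", "G2")]
        ]
        probes = _probes(
            [("a", "G1", 0.8), ("b", "G1", 0.7), ("c", "G2", 0.9), ("d", "G2", 0.6)]
        )
        report = validate_gold_standard(probes, labels)
        assert all(m.sensitivity == 1.0 and m.cm.fp == 0 for m in report.metrics)
        assert report.identified_fraction == 1.0

    def test_high_threshold_empties_predictions(self):
        labels = [
            FDALabelEntry(drug_id=d, target_gene="G1") for d in ("a", "b")
        ]
        probes = _probes([("a", "G1", 0.8), ("b", "G1", 0.7)])
        report = validate_gold_standard(probes, labels, ThresholdPolicy(tau=0.9))
        assert all(m.cm.tp == 0 and m.cm.fp == 0 for m in report.metrics)

    def test_threshold_monotonicity(self):
        rnd = random.Random(3)
        probes = _probes(
            [(f"d{i}", f"G{i % 3}", round(rnd.random(), 3)) for i in range(60)]
        )
        labels = [
            FDALabelEntry(drug_id=f"d{i}", target_gene=f"G{i % 3}") for i in range(6)
        ]
        universe = build_drug_universe(probes, [f"d{i}" for i in range(60)])
        prev = None
        for tau in (0.1, 0.3, 0.5, 0.7, 0.9):
            total_predicted = sum(
                len(
                    predicted_drugs_for_gene(
                        g, probes, universe, ThresholdPolicy(tau=tau)
                    )
                )
                for g in ("G0", "G1", "G2")
            )
            if prev is not None:
                assert total_predicted <= prev
            prev = total_predicted

    def test_cell_sum_conservation(self):
        rnd = random.Random(5)
        probes = _probes(
            [(f"d{i}", f"G{i % 4}", round(rnd.random(), 3)) for i in range(80)]
        )
        labels = [
            FDALabelEntry(drug_id=f"d{i}", target_gene=f"G{i % 4}") for i in range(8)
        ]
        report = validate_gold_standard(
            probes, labels, fda_drugs=[f"d{i}" for i in range(80)]
        )
        sizes = {m.cm.total for m in report.metrics}
        assert sizes == {len(report.universe)}

    def test_planted_recovery_from_generator(self):
        cfg = synth.make_config(
            seed=13,
            n_genes=8,
            n_compounds=50,
            score_noise_sd=0.0,
            planted_pairs=[
                ("DRUG001", "GENE001"),
                ("DRUG002", "GENE001"),
                ("DRUG003", "GENE002"),
                ("DRUG004", "GENE002"),
            ],
        )
        probes, _ = synth.gen_probe_table(cfg)
        labels = synth.gen_fda_labels(cfg)
        report = validate_gold_standard(
            probes, labels, fda_drugs=synth.fda_drug_list(cfg)
        )
        assert {m.gene for m in report.metrics} == {"GENE001", "GENE002"}
        assert all(m.sensitivity == 1.0 and m.cm.fp == 0 for m in report.metrics)
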