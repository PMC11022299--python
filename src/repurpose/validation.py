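"""Validation of a probe-score table against an FDA drug-biomarker gold standard.

The drug universe is the intersection of FDA-approved drugs and compounds
indexed in the probe table; within that universe, drugs whose global score
for a gene passes the inclusion threshold are "predicted" for the gene, the
FDA-labelled drugs for the gene are the truth set, and a per-gene confusion
matrix (summing to the universe size, identically for every gene) yields
sensitivity, specificity and precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

from repurpose.errors import AnalysisError, ConfigError
from repurpose.tables import FDALabelEntry, ProbeRecord


class Comparator(str, enum.Enum):
    greater = "greater"
    greater_or_equal = "greater_or_equal"


class ThresholdPolicy(BaseModel):
    """Score threshold for compound inclusion (default: global score > 0.25)."""

    tau: float = Field(default=0.25, gt=0.0, lt=1.0)
    comparator: Comparator = Comparator.greater

    def passes(self, score: float) -> bool:
        if self.comparator is Comparator.greater:
            return score > self.tau
        return score >= self.tau


@dataclass(frozen=True)
class ConfusionMatrix:
    gene: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ValidationMetrics:
    """Per-gene classification metrics; None marks an undefined ratio."""

    gene: str
    cm: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the display convention for metric tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def build_drug_universe(
    probe_table: Sequence[ProbeRecord], fda_drugs: Iterable[str | FDALabelEntry]
) -> set[str]:
    """Intersection of FDA drug ids with compounds in the probe table.

    This set is the denominator universe for every gene's confusion matrix;
    compounds missing from either source are not evaluable.
    """
    fda_ids = {d.drug_id if isinstance(d, FDALabelEntry) else d for d in fda_drugs}
    probe_ids = {r.compound_id for r in probe_table}
    if not fda_ids or not probe_ids:
        raise AnalysisError("probe table and FDA drug list must both be non-empty")
    universe = fda_ids & probe_ids
    if not universe:
        raise AnalysisError(
            "no drug is indexed in both the FDA list and the probe table"
        )
    return universe


def predicted_drugs_for_gene(
    gene: str,
    probe_table: Sequence[ProbeRecord],
    universe: set[str],
    policy: ThresholdPolicy,
) -> set[str]:
    """Universe drugs whose score for ``gene`` passes the threshold."""
    return {
        r.compound_id
        for r in probe_table
        if r.target_gene == gene
        and r.compound_id in universe
        and policy.passes(r.global_score)
    }


def eligible_genes(
    fda_labels: Sequence[FDALabelEntry], min_therapies: int = 2
) -> set[str]:
    """Genes with at least ``min_therapies`` distinct labelled drugs.

    The default of 2 keeps only biomarkers with more than one approved
    therapy, the minimum held to carry enough signal for a per-gene
    confusion matrix.
    """
    if min_therapies < 1:
        raise ConfigError("min_therapies must be >= 1")
    drugs_per_gene: dict[str, set[str]] = {}
    for lab in fda_labels:
        drugs_per_gene.setdefault(lab.target_gene, set()).add(lab.drug_id)
    return {g for g, drugs in drugs_per_gene.items() if len(drugs) >= min_therapies}


def confusion_matrix_for_gene(
    gene: str, predicted: set[str], truth: set[str], universe: set[str]
) -> ConfusionMatrix:
    """Four-way classification of every universe drug for one gene."""
    if not truth <= universe:
        missing = sorted(truth - universe)
        raise AnalysisError(
            f"gold-standard drugs absent from universe for {gene}: {missing}"
        )
    if not predicted <= universe:
        raise AnalysisError(f"predicted set for {gene} escapes the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionMatrix(gene=gene, tp=tp, fp=fp, tn=tn, fn=fn)


def classification_metrics(cm: ConfusionMatrix) -> ValidationMetrics:
    """Sensitivity, specificity, precision from one confusion matrix.

    Ratios with a zero denominator are undefined (None) rather than 0:
    a gene with no predictions has no measurable precision.
    """
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    prec = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    return ValidationMetrics(
        gene=cm.gene, cm=cm, sensitivity=sens, specificity=spec, precision=prec
    )


@dataclass
class GoldStandardReport:
    """Full validation output: per-gene metrics plus table-level statistics.

    ``identified_fraction`` is the share of gold-standard drug-gene pairs
    present anywhere in the probe table at any score (presence, not
    threshold inclusion — a pair can be indexed at a score below the
    inclusion threshold and still count here).  ``top10_fraction`` is the
    share ranked within the top ten probes for their gene.
    """

    metrics: list[ValidationMetrics]
    universe: set[str]
    identified_fraction: float
    top10_fraction: float


def validate_gold_standard(
    probe_table: Sequence[ProbeRecord],
    fda_labels: Sequence[FDALabelEntry],
    policy: ThresholdPolicy | None = None,
    min_therapies: int = 2,
    fda_drugs: Iterable[str | FDALabelEntry] | None = None,
) -> GoldStandardReport:
    """Run the whole gold-standard validation and return per-gene metrics.

    ``fda_drugs`` is the full approved-drug list defining the universe
    (defaults to the drugs carried on the labels, but a regulatory drug
    list is normally much larger than the biomarker-labelled subset and
    should be passed explicitly for realistic true-negative counts).
    """
    policy = policy or ThresholdPolicy()
    universe = build_drug_universe(
        probe_table, fda_labels if fda_drugs is None else fda_drugs
    )
    genes = eligible_genes(fda_labels, min_therapies)

    truth_by_gene: dict[str, set[str]] = {}
    for lab in fda_labels:
        if lab.drug_id in universe:
            truth_by_gene.setdefault(lab.target_gene, set()).add(lab.drug_id)

    metrics = []
    for gene in sorted(genes):
        truth = truth_by_gene.get(gene, set())
        predicted = predicted_drugs_for_gene(gene, probe_table, universe, policy)
        cm = confusion_matrix_for_gene(gene, predicted, truth, universe)
        metrics.append(classification_metrics(cm))

    indexed = {(r.compound_id, r.target_gene) for r in probe_table}
    top10 = {
        (r.compound_id, r.target_gene)
        for r in probe_table
        if r.rank_in_target is not None and r.rank_in_target <= 10
    }
    gold_pairs = {(lab.drug_id, lab.target_gene) for lab in fda_labels}
    n_gold = len(gold_pairs)
    identified = sum(1 for p in gold_pairs if p in indexed)
    in_top10 = sum(1 for p in gold_pairs if p in top10)
    return GoldStandardReport(
        metrics=metrics,
        universe=universe,
        identified_fraction=identified / n_gold if n_gold else 0.0,
        top10_fraction=in_top10 / n_gold if n_gold else 0.0,
    )


def metrics_table_rows(metrics: Sequence[ValidationMetrics]) -> list[dict]:
    """Display rows with 2-decimal half-up rounding, blank for undefined."""
    rows = []
    for m in metrics:
        rows.append(
            {
                "gene": m.gene,
                "tp": m.cm.tp,
                "fp": m.cm.fp,
                "tn": m.cm.tn,
                "fn": m.cm.fn,
                "sensitivity": "" if m.sensitivity is None else round_half_up(m.sensitivity),
                "specificity": "" if m.specificity is None else round_half_up(m.specificity),
                "precision": "" if m.precision is None else round_half_up(m.precision),
            }
        )
    return rows
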