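"""Tiered triage of GOF variants into repurposing events.

The cascade is fixed: a gene with an approved biomarker-matched therapy
(Tier I) is excluded first; surviving events with an active clinical-trial
programme are "trial-level"; known off-label drug-target interactions are
"off-label"; everything else is "novel".  Candidate drugs come from the
probe table restricted to the FDA universe and the score threshold.
"""

from __future__ import annotations

import enum
import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from repurpose.errors import AnalysisError
from repurpose.tables import (
    EvidenceIndex,
    FDALabelEntry,
    MutationType,
    PatientReport,
    ProbeRecord,
)
from repurpose.validation import ThresholdPolicy, build_drug_universe
from repurpose.variants import FunctionalAnnotation, FunctionalClass


class EventCategory(str, enum.Enum):
    tier1_excluded = "tier1_excluded"
    trial_level = "trial_level"
    off_label = "off_label"
    novel = "novel"


#: Categories that represent an actionable off-label opportunity for a
#: patient (everything past the trial-evidence gate).
ACTIONABLE_CATEGORIES = frozenset({EventCategory.off_label, EventCategory.novel})

DEFAULT_TIER1_GENES = frozenset(
    {"KRAS", "ERBB2", "EGFR", "BRAF", "KIT", "CDK4", "CDK6", "PIK3CA"}
)


@dataclass(frozen=True)
class TierOnePolicy:
    """Genes whose aberrations already have approved matched therapies.

    Exclusion applies if the gene is in ``genes`` or in the cross-referenced
    FDA biomarker gene set.
    """

    genes: frozenset[str] = DEFAULT_TIER1_GENES
    fda_biomarker_genes: frozenset[str] = frozenset()

    def excludes(self, gene: str) -> bool:
        return gene in self.genes or gene in self.fda_biomarker_genes


@dataclass(frozen=True)
class RepurposingEvent:
    patient_id: str
    gene: str
    mutation_type: MutationType
    candidate_drugs: tuple[tuple[str, float], ...]  # descending score
    category: EventCategory
    sources: frozenset[str] = frozenset({"probe_db"})


def find_candidate_drugs(
    gene: str,
    probe_table: Sequence[ProbeRecord],
    universe: set[str],
    policy: ThresholdPolicy,
) -> list[tuple[str, float]]:
    """FDA-universe drugs passing the threshold for ``gene``, best first."""
    hits = [
        (r.compound_id, r.global_score)
        for r in probe_table
        if r.target_gene == gene
        and r.compound_id in universe
        and policy.passes(r.global_score)
    ]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def categorize_event(
    gene: str,
    candidates: Sequence[tuple[str, float]],
    tier1: TierOnePolicy,
    evidence: EvidenceIndex,
) -> EventCategory:
    """Fixed-order cascade; genes absent from the index read as no evidence."""
    if not candidates:
        raise AnalysisError("categorize_event requires a non-empty candidate list")
    if tier1.excludes(gene):
        return EventCategory.tier1_excluded
    flags = evidence.lookup(gene)
    if flags.has_trial_evidence:
        return EventCategory.trial_level
    if flags.known_off_label:
        return EventCategory.off_label
    return EventCategory.novel


@dataclass
class TriageResult:
    """Everything the triage stage produces for one cohort."""

    events: list[RepurposingEvent]
    unique_events: list[RepurposingEvent]  # one representative per dedup key
    dedup_key: str
    patients_with_actionable: set[str]
    n_patients: int

    @property
    def actionable_patient_fraction(self) -> float:
        if self.n_patients == 0:
            return 0.0
        return len(self.patients_with_actionable) / self.n_patients

    def category_counts(self, unique: bool = False) -> dict[str, int]:
        pool = self.unique_events if unique else self.events
        counts = Counter(e.category.value for e in pool)
        return {c.value: counts.get(c.value, 0) for c in EventCategory}


def _dedup(
    events: Sequence[RepurposingEvent], key: str
) -> list[RepurposingEvent]:
    seen: set = set()
    out = []
    for e in events:
        k = e.gene if key == "gene" else (e.gene, e.mutation_type)
        if k not in seen:
            seen.add(k)
            out.append(e)
    return out


def triage_cohort(
    reports: Sequence[PatientReport],
    annotations: Sequence[FunctionalAnnotation],
    probe_table: Sequence[ProbeRecord],
    fda_labels: Sequence[FDALabelEntry],
    evidence: EvidenceIndex,
    tier1: TierOnePolicy | None = None,
    policy: ThresholdPolicy | None = None,
    dedup_key: str = "gene_type",
    top_n: int | None = None,
) -> TriageResult:
    """Turn GOF-annotated variants into categorised repurposing events.

    Only variants annotated GOF enter; a variant yields an event only if at
    least one FDA-universe drug passes the score threshold for its gene.
    ``dedup_key`` is ``gene_type`` (gene, mutation type) or ``gene``.
    ``top_n`` truncates each event's candidate list for reporting (None
    keeps all candidates).
    """
    if dedup_key not in {"gene_type", "gene"}:
        raise AnalysisError(f"unknown dedup key {dedup_key!r}")
    tier1 = tier1 or TierOnePolicy()
    policy = policy or ThresholdPolicy()
    universe = build_drug_universe(probe_table, fda_labels)

    # VariantCall is frozen/hashable, so annotations join by value; duplicate
    # identical variants share one (equivalent) annotation.
    by_variant = {a.variant: a for a in annotations}
    candidates_cache: dict[str, list[tuple[str, float]]] = {}
    events: list[RepurposingEvent] = []
    for report in reports:
        for variant in report.variants:
            ann = by_variant.get(variant)
            if ann is None or ann.functional_class is not FunctionalClass.GOF:
                continue
            if variant.gene not in candidates_cache:
                candidates_cache[variant.gene] = find_candidate_drugs(
                    variant.gene, probe_table, universe, policy
                )
            candidates = candidates_cache[variant.gene]
            if not candidates:
                continue  # no probe-identified drug -> no event
            category = categorize_event(variant.gene, candidates, tier1, evidence)
            shown = candidates if top_n is None else candidates[:top_n]
            events.append(
                RepurposingEvent(
                    patient_id=report.patient_id,
                    gene=variant.gene,
                    mutation_type=variant.mutation_type,
                    candidate_drugs=tuple(shown),
                    category=category,
                )
            )

    unique_events = _dedup(events, dedup_key)
    actionable = {
        e.patient_id for e in events if e.category in ACTIONABLE_CATEGORIES
    }
    return TriageResult(
        events=events,
        unique_events=unique_events,
        dedup_key=dedup_key,
        patients_with_actionable=actionable,
        n_patients=len(reports),
    )


def overlap_summary(
    event_sets: Mapping[str, set],
) -> dict[frozenset[str], int]:
    """Venn-region counts over the unique-event sets of >= 2 sources.

    Returns a map from each non-empty source subset to the number of
    elements belonging to exactly those sources; region counts sum to the
    size of the union.
    """
    if len(event_sets) < 2:
        raise AnalysisError("overlap_summary needs at least two sources")
    sources = sorted(event_sets)
    regions: dict[frozenset[str], int] = {
        frozenset(c): 0
        for r in range(1, len(sources) + 1)
        for c in itertools.combinations(sources, r)
    }
    universe = set().union(*event_sets.values())
    for item in universe:
        membership = frozenset(s for s in sources if item in event_sets[s])
        regions[membership] += 1
    return regions
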