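"""Enumeration of the repurposable genome and its pan-cancer mutation burden.

The repurposable genome is every gene having at least one FDA-approved
compound whose probe global score passes the inclusion threshold, after
removing combinations already carried on an FDA label for that gene.  Its
clinical reach is estimated as the fraction of tumour samples in a binary
mutation matrix carrying a call in any repurposable gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from repurpose.errors import AnalysisError, ConfigError
from repurpose.tables import FDALabelEntry, MutationMatrix, ProbeRecord
from repurpose.validation import build_drug_universe


@dataclass
class RepurposableGenome:
    """Per-gene surviving compounds (descending score) plus the event count.

    ``n_theoretical_events`` counts all surviving gene-drug combinations,
    before any display top-N truncation.
    """

    entries: dict[str, list[tuple[str, float]]]
    threshold_used: float
    n_theoretical_events: int

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    def top_compounds(self, n: int = 1) -> dict[str, list[tuple[str, float]]]:
        return {g: lst[:n] for g, lst in self.entries.items()}


def enumerate_repurposable(
    probe_table: Sequence[ProbeRecord],
    fda_drugs: Iterable[str | FDALabelEntry],
    fda_labels: Sequence[FDALabelEntry],
    tau: float = 0.25,
    exclusion: str = "pair",
) -> RepurposableGenome:
    """All FDA-approved gene-drug combinations with global score > tau.

    ``exclusion`` controls how FDA-labelled knowledge removes candidates:
    ``pair`` (default) drops only the labelled (drug, gene) combination,
    ``drug`` drops a labelled drug from every gene.  Genes with no
    surviving compound are omitted.
    """
    if exclusion not in {"pair", "drug"}:
        raise ConfigError(f"unknown exclusion mode {exclusion!r}")
    universe = build_drug_universe(probe_table, fda_drugs)
    labelled_pairs = {(lab.drug_id, lab.target_gene) for lab in fda_labels}
    labelled_drugs = {lab.drug_id for lab in fda_labels}

    entries: dict[str, list[tuple[str, float]]] = {}
    n_events = 0
    for rec in probe_table:
        if rec.compound_id not in universe or rec.global_score <= tau:
            continue
        if exclusion == "pair" and (rec.compound_id, rec.target_gene) in labelled_pairs:
            continue
        if exclusion == "drug" and rec.compound_id in labelled_drugs:
            continue
        entries.setdefault(rec.target_gene, []).append(
            (rec.compound_id, rec.global_score)
        )
        n_events += 1
    for gene in entries:
        entries[gene].sort(key=lambda t: (-t[1], t[0]))
    return RepurposableGenome(
        entries=entries, threshold_used=tau, n_theoretical_events=n_events
    )


def mutation_burden(
    genome: RepurposableGenome, mm: MutationMatrix
) -> tuple[int, int, float]:
    """Samples with >= 1 call in any repurposable gene: (n_hit, n_total, fraction)."""
    if mm.calls.empty:
        raise AnalysisError("mutation matrix is empty")
    genes = [g for g in genome.genes if g in mm.calls.columns]
    n_total = len(mm.samples)
    if not genes:
        return 0, n_total, 0.0
    n_hit = int((mm.calls[genes].sum(axis=1) > 0).sum())
    return n_hit, n_total, n_hit / n_total


def high_confidence_subset(
    genome: RepurposableGenome, tau_high: float = 0.7
) -> list[tuple[str, str]]:
    """(drug, gene) pairs with score > tau_high, ready for the concordance screen."""
    if tau_high <= genome.threshold_used:
        raise ConfigError(
            f"tau_high ({tau_high}) must exceed the enumeration threshold "
            f"({genome.threshold_used})"
        )
    pairs = [
        (drug, gene)
        for gene, lst in genome.entries.items()
        for drug, score in lst
        if score > tau_high
    ]
    return sorted(pairs)
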