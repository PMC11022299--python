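"""End-to-end pipeline driver: synth -> validate -> triage -> screen -> genome.

Every run writes its stage artefacts to one output directory plus a
``manifest.json`` recording the config hash and a content hash per output
file; re-running with the same config and seed reproduces the stochastic
stages byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import pydantic
from pydantic import BaseModel, Field
import yaml

from repurpose import synth
from repurpose.concordance import concordance_screen, results_frame
from repurpose.errors import ConfigError, RepurposeError
from repurpose.genome import enumerate_repurposable, high_confidence_subset, mutation_burden
from repurpose.tables import (
    read_cell_line_panel,
    read_evidence_index,
    read_fda_labels,
    read_mutation_matrix,
    read_patient_reports,
    read_probe_table,
    write_cell_line_panel,
    write_mutation_matrix,
    write_patient_reports,
    write_table,
)
from repurpose.triage import TierOnePolicy, overlap_summary, triage_cohort
from repurpose.validation import (
    ThresholdPolicy,
    metrics_table_rows,
    round_half_up,
    validate_gold_standard,
)
from repurpose.variants import classify_cohort, summarize_gof

#: Default planted truth: three probe-target genes with two approved drugs
#: each (two therapies being the eligibility floor for per-gene metrics),
#: reused as planted sensitivity-covariate dependencies in the panel.
DEFAULT_PLANTED = [
    ("DRUG001", "GENE001"),
    ("DRUG002", "GENE001"),
    ("DRUG003", "GENE002"),
    ("DRUG004", "GENE002"),
    ("DRUG005", "GENE003"),
    ("DRUG006", "GENE003"),
]

#: Default off-label plants: high probe scores with no FDA label, the
#: repurposable-genome signal (oncogene-role genes so triage can hit them).
DEFAULT_OFFLABEL = [
    ("DRUG010", "GENE004"),
    ("DRUG011", "GENE005"),
    ("DRUG012", "GENE006"),
    ("DRUG013", "GENE007"),
]


class RunConfig(BaseModel):
    """Serialisable configuration for one pipeline run."""

    seed: int = 0
    generator: dict = Field(default_factory=dict)  # GeneratorConfig overrides
    tau: float = 0.25
    tau_high: float = 0.7
    alpha: float = 0.05
    min_therapies: int = 2
    dedup_key: str = "gene_type"
    tier1_genes: list[str] = Field(default_factory=lambda: ["GENE001"])

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**raw)
        except pydantic.ValidationError as exc:
            raise ConfigError(str(exc)) from None

    def generator_config(self) -> synth.GeneratorConfig:
        kwargs = dict(self.generator)
        kwargs.setdefault("planted_pairs", DEFAULT_PLANTED)
        kwargs.setdefault("planted_offlabel_pairs", DEFAULT_OFFLABEL)
        kwargs["seed"] = self.seed
        return synth.make_config(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class StageLog:
    name: str
    n_in: int
    n_out: int


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all five stages; returns the manifest dict (also written to disk).

    Any stage failure aborts with the failing stage named in the raised
    error.  Record counts in and out of each stage are logged in the
    manifest, giving the run a CONSORT-style audit trail.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[StageLog] = []
    outputs: list[Path] = []
    current = "synth"
    try:
        # --- synth -----------------------------------------------------
        cfg = config.generator_config()
        probes, planted_pairs = synth.gen_probe_table(cfg)
        labels = synth.gen_fda_labels(cfg)
        reports, variant_truth = synth.gen_patient_reports(cfg)
        kb = synth.gen_knowledge_base(cfg)
        evidence = synth.gen_evidence_index(cfg)
        panel, planted_dep = synth.gen_cell_line_panel(
            cfg, [*cfg.planted_pairs, *cfg.planted_offlabel_pairs]
        )
        mm = synth.gen_mutation_matrix(cfg)

        write_table(probes, out / "probes.tsv")
        write_table(labels, out / "fda_labels.tsv")
        (out / "fda_drugs.txt").write_text("\n".join(synth.fda_drug_list(cfg)) + "\n")
        write_patient_reports(reports, out / "cohort.json")
        write_table(sorted(evidence.entries.values(), key=lambda e: e.gene), out / "evidence.tsv")
        kb.to_yaml(out / "knowledge_base.yaml")
        write_cell_line_panel(panel, out / "panel")
        write_mutation_matrix(mm, out / "mutations.tsv")
        truth = {
            "planted_pairs": [list(p) for p in planted_pairs],
            "planted_dependencies": [list(p) for p in planted_dep],
            "n_planted_gof": sum(1 for t in variant_truth if t.planted_class == "GOF"),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
        outputs += [
            out / "probes.tsv", out / "fda_labels.tsv", out / "fda_drugs.txt",
            out / "cohort.json", out / "evidence.tsv", out / "knowledge_base.yaml",
            out / "panel" / "expression.tsv", out / "panel" / "dependency.tsv",
            out / "panel" / "sensitivity.tsv", out / "mutations.tsv",
            out / "truth.json",
        ]
        stages.append(StageLog("synth", 0, len(probes) + len(reports)))

        # --- validate ---------------------------------------------------
        current = "validate"
        policy = ThresholdPolicy(tau=config.tau)
        report = validate_gold_standard(
            probes, labels, policy,
            min_therapies=config.min_therapies,
            fda_drugs=synth.fda_drug_list(cfg),
        )
        rows = metrics_table_rows(report.metrics)
        pd.DataFrame(rows).to_csv(out / "validation_metrics.tsv", sep="\t", index=False)
        (out / "validation_summary.json").write_text(
            json.dumps(
                {
                    "universe_size": len(report.universe),
                    "identified_fraction": report.identified_fraction,
                    "top10_fraction": report.top10_fraction,
                },
                indent=1,
            )
            + "\n"
        )
        outputs += [out / "validation_metrics.tsv", out / "validation_summary.json"]
        stages.append(StageLog("validate", len(probes), len(rows)))

        # --- triage -----------------------------------------------------
        current = "triage"
        annotations = classify_cohort(reports, kb)
        gof_summary = summarize_gof(reports, annotations)
        tier1 = TierOnePolicy(genes=frozenset(config.tier1_genes))
        triage = triage_cohort(
            reports, annotations, probes, labels, evidence,
            tier1=tier1, policy=policy, dedup_key=config.dedup_key,
        )
        _write_events(triage.events, out / "events.tsv")
        _write_events(triage.unique_events, out / "unique_events.tsv")
        per_patient = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in reports],
                "actionable": [
                    r.patient_id in triage.patients_with_actionable for r in reports
                ],
            }
        )
        per_patient.to_csv(out / "per_patient.tsv", sep="\t", index=False)
        unique_keys = {(e.gene, e.mutation_type.value) for e in triage.unique_events}
        trial_genes = {
            g for g, e in evidence.entries.items() if e.has_trial_evidence
        }
        venn = overlap_summary(
            {
                "probe_db": unique_keys,
                "evidence_db": {k for k in unique_keys if k[0] in trial_genes},
            }
        )
        (out / "venn.json").write_text(
            json.dumps({"+".join(sorted(k)): v for k, v in venn.items()}, indent=1)
            + "\n"
        )
        (out / "triage_summary.json").write_text(
            json.dumps(
                {
                    "n_events": len(triage.events),
                    "n_unique_events": len(triage.unique_events),
                    "category_counts": triage.category_counts(),
                    "unique_category_counts": triage.category_counts(unique=True),
                    "n_actionable_patients": len(triage.patients_with_actionable),
                    "actionable_patient_fraction": triage.actionable_patient_fraction,
                    "n_variants": gof_summary.n_variants,
                    "n_gof": gof_summary.n_gof,
                    "gof_by_type_pct": gof_summary.by_type_pct,
                },
                indent=1,
            )
            + "\n"
        )
        outputs += [
            out / "events.tsv", out / "unique_events.tsv", out / "per_patient.tsv",
            out / "venn.json", out / "triage_summary.json",
        ]
        stages.append(StageLog("triage", gof_summary.n_gof, len(triage.events)))

        # --- screen -----------------------------------------------------
        current = "screen"
        pairs = [(d, g) for d, g in [*cfg.planted_pairs, *cfg.planted_offlabel_pairs]]
        results, summary = concordance_screen(pairs, panel, alpha=config.alpha)
        frame = results_frame(results)
        frame.to_csv(out / "screen_results.tsv", sep="\t", index=False)
        (out / "screen_summary.json").write_text(
            json.dumps(summary.__dict__, indent=1) + "\n"
        )
        outputs += [out / "screen_results.tsv", out / "screen_summary.json"]
        stages.append(StageLog("screen", len(pairs), len(results)))

        # --- genome -----------------------------------------------------
        current = "genome"
        genome = enumerate_repurposable(
            probes, synth.fda_drug_list(cfg), labels, tau=config.tau
        )
        n_hit, n_total, fraction = mutation_burden(genome, mm)
        hi = high_confidence_subset(genome, tau_high=config.tau_high)
        genome_rows = [
            {"gene": g, "drug_id": d, "global_score": s}
            for g, lst in sorted(genome.entries.items())
            for d, s in lst
        ]
        pd.DataFrame(genome_rows, columns=["gene", "drug_id", "global_score"]).to_csv(
            out / "genome.tsv", sep="\t", index=False
        )
        pd.DataFrame(hi, columns=["drug_id", "gene"]).to_csv(
            out / "high_confidence_pairs.tsv", sep="\t", index=False
        )
        (out / "burden.json").write_text(
            json.dumps(
                {
                    "n_theoretical_events": genome.n_theoretical_events,
                    "n_hit": n_hit,
                    "n_total": n_total,
                    "fraction": fraction,
                    "percent": round_half_up(100 * fraction, 0),
                },
                indent=1,
            )
            + "\n"
        )
        outputs += [out / "genome.tsv", out / "high_confidence_pairs.tsv", out / "burden.json"]
        stages.append(StageLog("genome", genome.n_theoretical_events, n_hit))
    except RepurposeError as exc:
        raise type(exc)(f"stage {current!r} failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [
            {"name": s.name, "records_in": s.n_in, "records_out": s.n_out}
            for s in stages
        ],
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in outputs
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def _write_events(events, path: Path) -> None:
    rows = [
        {
            "patient_id": e.patient_id,
            "gene": e.gene,
            "mutation_type": e.mutation_type.value,
            "category": e.category.value,
            "candidate_drugs": ";".join(f"{d}:{s:.4f}" for d, s in e.candidate_drugs),
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=["patient_id", "gene", "mutation_type", "category", "candidate_drugs"],
    ).to_csv(path, sep="\t", index=False)


def render_report(out_dir: str | Path) -> str:
    """Human-readable run summary assembled from the stage artefacts.

    Absent stages are marked rather than failing, so a partial run still
    renders.  Counts are recomputed from the raw TSVs, not copied from the
    stage summaries.
    """
    out = Path(out_dir)
    lines: list[str] = ["# Repurposing pipeline report", ""]

    path = out / "validation_metrics.tsv"
    if path.exists():
        df = pd.read_csv(path, sep="\t")
        lines.append("## Gold-standard validation (per-gene metrics)")
        lines.append(df.to_string(index=False))
        summary = json.loads((out / "validation_summary.json").read_text())
        lines.append(
            f"universe: {summary['universe_size']} drugs; "
            f"gold pairs indexed: {summary['identified_fraction']:.0%}; "
            f"in top-10 probes: {summary['top10_fraction']:.0%}"
        )
    else:
        lines.append("## Gold-standard validation: ABSENT")
    lines.append("")

    path = out / "events.tsv"
    if path.exists():
        events = pd.read_csv(path, sep="\t")
        unique = pd.read_csv(out / "unique_events.tsv", sep="\t")
        per_patient = pd.read_csv(out / "per_patient.tsv", sep="\t")
        lines.append("## Triage (CONSORT counts, recomputed from events table)")
        lines.append(f"events: {len(events)}; unique events: {len(unique)}")
        cats = events["category"].value_counts().to_dict() if len(events) else {}
        for cat in ("tier1_excluded", "trial_level", "off_label", "novel"):
            lines.append(f"  {cat}: {cats.get(cat, 0)}")
        n_act = int(per_patient["actionable"].sum()) if len(per_patient) else 0
        lines.append(
            f"patients with an off-label/novel event: {n_act}/{len(per_patient)}"
            f" ({100 * n_act / max(len(per_patient), 1):.0f}%)"
        )
        if len(events):
            comp = events.groupby("mutation_type").size().sort_values(ascending=False)
            lines.append("event composition by mutation type:")
            for mtype, n in comp.items():
                lines.append(f"  {mtype}: {n} ({100 * n / len(events):.1f}%)")
    else:
        lines.append("## Triage: ABSENT")
    lines.append("")

    path = out / "screen_results.tsv"
    if path.exists():
        screen = pd.read_csv(path, sep="\t")
        lines.append("## Functional-concordance screen")
        lines.append(screen.to_string(index=False))
    else:
        lines.append("## Functional-concordance screen: ABSENT")
    lines.append("")

    path = out / "burden.json"
    if path.exists():
        genome_df = pd.read_csv(out / "genome.tsv", sep="\t")
        burden = json.loads(path.read_text())
        lines.append("## Repurposable genome")
        lines.append(
            f"theoretical events (recount): {len(genome_df)}; "
            f"genes: {genome_df['gene'].nunique() if len(genome_df) else 0}"
        )
        lines.append(
            f"mutation burden: {burden['n_hit']}/{burden['n_total']} samples "
            f"({burden['percent']:.0f}%)"
        )
    else:
        lines.append("## Repurposable genome: ABSENT")
    lines.append("")
    return "\n".join(lines)
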