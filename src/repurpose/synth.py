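"""Seeded generators for every input table the pipeline consumes.

Each generator draws from its own counter-based random stream derived from
the single config seed, so adding one generator call never perturbs the
output of another.  Planted signals (true drug-target pairs, GOF variants,
monotone sensitivity-covariate relationships) are returned alongside the
data as explicit truth records, so recovery can be tested end to end.

Default parameters emulate the study conditions of a real-world off-target
repurposing screen: a 94-report NGS cohort averaging ~4.2 reported variants
per report of which 45.4 % are gain-of-function, a GOF type mix dominated
by amplification (58.3 %), a probe database whose decoy scores sit far
below the 0.25 inclusion threshold while planted true pairs score above
0.6, and cell-line panels of 200 lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pydantic
from pydantic import BaseModel, Field
from scipy import stats

from repurpose.errors import ConfigError
from repurpose.tables import (
    CellLinePanel,
    EvidenceEntry,
    EvidenceIndex,
    FDALabelEntry,
    MutationMatrix,
    MutationType,
    PatientReport,
    ProbeRecord,
    SensitivityMetric,
    VariantCall,
)
from repurpose.tables import assign_ranks
from repurpose.variants import FunctionalClass, KnowledgeBase, Pathogenicity

# stable stream ids: one per generator
_STREAMS = {
    "probe": 1,
    "reports": 2,
    "panel": 3,
    "mutation": 4,
    "evidence": 5,
}

#: Average standardised gap between consecutive quartile means of a
#: standard normal covariate: (E[X|Q4] - E[X|Q1]) / 3.
QUARTILE_SPAN = (2 * stats.norm.pdf(stats.norm.ppf(0.25)) / 0.25) / 3

_GOF_TYPES = ("amplification", "nsSNV", "fusion", "other")


class GeneratorConfig(BaseModel):
    """Single source of truth for all synthetic inputs.

    ``gof_type_mix`` is the multinomial distribution of mutation types
    among planted GOF variants, over (amplification, nsSNV, fusion, other).
    ``planted_effect_size`` is the standardised mean shift in drug
    sensitivity per covariate quartile for planted drug-gene dependencies,
    in units of the unit-variance residual noise.
    """

    seed: int = 0
    n_genes: int = Field(default=60, ge=3)
    n_compounds: int = Field(default=200, ge=1)
    n_patients: int = Field(default=94, ge=1)
    n_cell_lines: int = Field(default=200, ge=8)
    n_tumor_samples: int = Field(default=2922, ge=1)
    planted_pairs: list[tuple[str, str]] = Field(default_factory=list)  # (drug, gene)
    # high-scoring pairs deliberately absent from the FDA label table:
    # the off-target signal the repurposable-genome stage exists to find
    planted_offlabel_pairs: list[tuple[str, str]] = Field(default_factory=list)
    planted_effect_size: float = 1.5
    planted_score_floor: float = 0.6
    decoy_score_mean: float = 0.05
    score_noise_sd: float = Field(default=0.02, ge=0.0)
    decoys_per_gene: int = Field(default=10, ge=0)
    gof_type_mix: tuple[float, float, float, float] = (0.583, 0.356, 0.033, 0.028)
    p_gof: float = Field(default=0.454, ge=0.0, le=1.0)
    mean_variants_per_report: float = Field(default=4.2, gt=0.0)
    tmb_log_mean: float = 1.1
    tmb_log_sd: float = Field(default=0.8, ge=0.0)
    per_gene_mutation_freq: dict[str, float] = Field(default_factory=dict)
    default_mutation_freq: float = Field(default=0.05, ge=0.0, le=1.0)
    p_trial_evidence: float = Field(default=0.3, ge=0.0, le=1.0)
    p_known_off_label: float = Field(default=0.2, ge=0.0, le=1.0)
    sensitivity_metric: SensitivityMetric = SensitivityMetric.log_fold_change

    @pydantic.field_validator("gof_type_mix")
    @classmethod
    def _mix_sums_to_one(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(p < 0 or p > 1 for p in v):
            raise ValueError("gof_type_mix probabilities must be in [0, 1]")
        total = sum(v)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"gof_type_mix must sum to 1, got {total}")
        return tuple(p / total for p in v)

    @pydantic.field_validator("planted_score_floor")
    @classmethod
    def _floor_in_open_unit(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("planted_score_floor must be in (0, 1)")
        return v

    @pydantic.field_validator("per_gene_mutation_freq")
    @classmethod
    def _freqs_in_unit(cls, v: dict[str, float]) -> dict[str, float]:
        for g, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mutation frequency for {g} outside [0, 1]: {p}")
        return v

    # --- derived name universes -------------------------------------
    @property
    def gene_names(self) -> list[str]:
        return [f"GENE{i:03d}" for i in range(1, self.n_genes + 1)]

    @property
    def compound_names(self) -> list[str]:
        return [f"DRUG{i:03d}" for i in range(1, self.n_compounds + 1)]

    @property
    def cell_line_names(self) -> list[str]:
        return [f"CL{i:03d}" for i in range(1, self.n_cell_lines + 1)]

    @property
    def oncogenes(self) -> list[str]:
        """First third of the gene universe plays the oncogene role."""
        return self.gene_names[: max(1, self.n_genes // 3)]

    @property
    def kinase_genes(self) -> list[str]:
        """Middle third plays the kinase role (disjoint from oncogenes)."""
        third = max(1, self.n_genes // 3)
        return self.gene_names[third : 2 * third]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def config_error_wrap(fn):
    """Re-raise pydantic validation failures as ConfigError (decorator)."""
    def wrapped(*args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except pydantic.ValidationError as exc:
            raise ConfigError(str(exc)) from None
    return wrapped


@config_error_wrap
def make_config(**kwargs) -> GeneratorConfig:
    """Build a GeneratorConfig, raising ConfigError on invalid values."""
    return GeneratorConfig(**kwargs)


# ---------------------------------------------------------------------------
# probe table


def _decoy_beta_params(cfg: GeneratorConfig) -> Optional[tuple[float, float]]:
    """Beta(a, b) matching the configured decoy mean and sd; None = point mass."""
    m, s = cfg.decoy_score_mean, cfg.score_noise_sd
    if s == 0.0:
        return None
    if s * s >= m * (1 - m):
        raise ConfigError(
            f"score_noise_sd {s} too large for decoy mean {m} (no valid Beta)"
        )
    a = m * (m * (1 - m) / (s * s) - 1.0)
    return a, a * (1 - m) / m


def decoy_tail_mass(cfg: GeneratorConfig, threshold: float = 0.25) -> float:
    """P(decoy score > threshold) under the configured decoy distribution."""
    params = _decoy_beta_params(cfg)
    if params is None:
        return float(cfg.decoy_score_mean > threshold)
    a, b = params
    return float(stats.beta.sf(threshold, a, b))


def gen_probe_table(
    cfg: GeneratorConfig,
) -> tuple[list[ProbeRecord], list[tuple[str, str]]]:
    """Probe-score table with planted true pairs and Beta-distributed decoys.

    Planted (drug, gene) pairs — both the FDA-labelled truth pairs and the
    off-label plants — score uniformly in [floor, 1]; decoys draw from a
    Beta distribution with the configured mean and sd, so all scores stay
    valid probe scores in [0, 1].  Returns (records, planted truth).
    """
    compounds = set(cfg.compound_names)
    genes = set(cfg.gene_names)
    for drug, gene in [*cfg.planted_pairs, *cfg.planted_offlabel_pairs]:
        if drug not in compounds or gene not in genes:
            raise ConfigError(
                f"planted pair ({drug}, {gene}) outside the compound x gene universe"
            )
    rng = cfg.rng("probe")
    params = _decoy_beta_params(cfg)
    planted = set(cfg.planted_pairs) | set(cfg.planted_offlabel_pairs)
    records: list[ProbeRecord] = []
    for drug, gene in sorted(planted):
        score = float(rng.uniform(cfg.planted_score_floor, 1.0))
        records.append(
            ProbeRecord(compound_id=drug, target_gene=gene, global_score=score)
        )
    for gene in cfg.gene_names:
        k = min(cfg.decoys_per_gene, cfg.n_compounds)
        chosen = rng.choice(cfg.compound_names, size=k, replace=False)
        for drug in chosen:
            if (str(drug), gene) in planted:
                continue
            if params is None:
                score = cfg.decoy_score_mean
            else:
                score = float(rng.beta(*params))
            records.append(
                ProbeRecord(compound_id=str(drug), target_gene=gene, global_score=score)
            )
    return assign_ranks(records), sorted(planted)


def gen_fda_labels(cfg: GeneratorConfig) -> list[FDALabelEntry]:
    """Gold-standard labels: exactly the planted drug-target pairs."""
    return [
        FDALabelEntry(drug_id=d, target_gene=g, modality="small_molecule")
        for d, g in sorted(set(cfg.planted_pairs))
    ]


def fda_drug_list(cfg: GeneratorConfig) -> list[str]:
    """The synthetic approved-drug universe: every generated compound."""
    return cfg.compound_names


# ---------------------------------------------------------------------------
# patient reports


@dataclass(frozen=True)
class PlantedVariant:
    """Truth record for one generated variant."""

    patient_id: str
    gene: str
    mutation_type: str
    planted_class: str  # "GOF" or "LOF"


def gen_knowledge_base(cfg: GeneratorConfig) -> KnowledgeBase:
    """Knowledge base aligned with the synthetic cohort's gene roles.

    Oncogene/kinase roles follow the config's deterministic gene split;
    every oncogene gets one synthetic hotspot change; "other"-type planted
    GOF variants are covered by curated overrides, mirroring how manual
    expert review enters the real workflow as data.
    """
    hotspots = frozenset((g, _hotspot_change(g)) for g in cfg.oncogenes)
    overrides = {
        (g, _OTHER_GOF_CHANGE): (FunctionalClass.GOF, Pathogenicity.possibly_pathogenic)
        for g in cfg.oncogenes
    }
    return KnowledgeBase(
        oncogenes=frozenset(cfg.oncogenes),
        kinase_genes=frozenset(cfg.kinase_genes),
        hotspot_changes=hotspots,
        curated_overrides=overrides,
    )


def _hotspot_change(gene: str) -> str:
    # one canonical activating change per synthetic oncogene
    return "G12D"


#: marker protein change for planted "other"-type GOF aberrations; the
#: synthetic knowledge base carries a curated override for it per oncogene
_OTHER_GOF_CHANGE = "X999_activating"


def gen_patient_reports(
    cfg: GeneratorConfig,
) -> tuple[list[PatientReport], list[PlantedVariant]]:
    """Synthetic NGS cohort with a multinomial GOF mutation-type mix.

    Per report the variant count is Poisson with the configured mean; each
    variant is GOF with probability ``p_gof`` and its type follows
    ``gof_type_mix``.  GOF variants are constructed so the rule cascade
    recovers them (amplifications; hotspot nsSNVs in oncogenes; fusions
    with kinase partners; "other" types covered by curated overrides).
    Non-GOF variants are truncating-class calls in non-oncogene genes.
    TMB is log-normal; no synthetic patient is MSI-high.
    """
    rng = cfg.rng("reports")
    mix = np.asarray(cfg.gof_type_mix)
    oncogenes = cfg.oncogenes
    kinases = cfg.kinase_genes
    lof_genes = cfg.gene_names[2 * max(1, cfg.n_genes // 3):] or cfg.gene_names
    reports: list[PatientReport] = []
    truth: list[PlantedVariant] = []
    for i in range(1, cfg.n_patients + 1):
        pid = f"PT{i:04d}"
        n_var = int(rng.poisson(cfg.mean_variants_per_report))
        variants: list[VariantCall] = []
        for _ in range(n_var):
            if rng.random() < cfg.p_gof:
                mtype = _GOF_TYPES[int(rng.choice(4, p=mix))]
                gene = str(rng.choice(oncogenes))
                if mtype == "amplification":
                    v = VariantCall(
                        patient_id=pid, gene=gene, mutation_type="amplification",
                        copy_number=float(np.round(rng.uniform(6, 30), 1)),
                    )
                elif mtype == "nsSNV":
                    v = VariantCall(
                        patient_id=pid, gene=gene, mutation_type="nsSNV",
                        protein_change=_hotspot_change(gene),
                        vaf=float(np.round(rng.uniform(0.05, 0.95), 3)),
                        fathmm_score=float(np.round(rng.normal(-2.0, 0.5), 2)),
                    )
                elif mtype == "fusion":
                    v = VariantCall(
                        patient_id=pid, gene=gene, mutation_type="fusion",
                        partner_gene=str(rng.choice(kinases)),
                    )
                else:  # "other": recovered only through a curated override
                    v = VariantCall(
                        patient_id=pid, gene=gene, mutation_type="other",
                        protein_change=_OTHER_GOF_CHANGE,
                    )
                truth.append(PlantedVariant(pid, gene, mtype, "GOF"))
            else:
                gene = str(rng.choice(lof_genes))
                mtype = ("truncating", "deletion", "splice")[int(rng.choice(3, p=[0.6, 0.25, 0.15]))]
                v = VariantCall(
                    patient_id=pid, gene=gene, mutation_type=mtype,
                    vaf=float(np.round(rng.uniform(0.05, 0.95), 3))
                    if mtype != "deletion" else None,
                )
                truth.append(PlantedVariant(pid, gene, mtype, "LOF"))
            variants.append(v)
        tmb = float(np.round(rng.lognormal(cfg.tmb_log_mean, cfg.tmb_log_sd), 2))
        reports.append(
            PatientReport(
                patient_id=pid, variants=variants,
                tmb_mut_per_mb=tmb, msi_status="low",
            )
        )
    return reports, truth


# ---------------------------------------------------------------------------
# cell-line panel


def gen_cell_line_panel(
    cfg: GeneratorConfig,
    planted_dependencies: Sequence[tuple[str, str]] = (),
    covariate: str = "expression",
) -> tuple[CellLinePanel, list[tuple[str, str]]]:
    """Expression / dependency / sensitivity matrices with planted signals.

    Covariates are standard normal per gene.  For each planted (drug,
    gene), sensitivity decreases linearly with the chosen covariate at a
    slope calibrated so the mean sensitivity shift between consecutive
    covariate quartiles equals ``planted_effect_size`` residual SDs; the
    residual noise has unit variance.  Non-planted drugs are pure noise.
    In AUC mode the slope sign flips (higher AUC = more sensitive).
    """
    if cfg.n_cell_lines < 8:
        raise ConfigError("n_cell_lines must be >= 8 (two lines per quartile)")
    if covariate not in {"expression", "dependency", "both"}:
        raise ConfigError(f"unknown covariate {covariate!r}")
    rng = cfg.rng("panel")
    lines = cfg.cell_line_names
    genes = cfg.gene_names
    drugs = cfg.compound_names
    gene_set, drug_set = set(genes), set(drugs)
    for d, g in planted_dependencies:
        if d not in drug_set or g not in gene_set:
            raise ConfigError(f"planted dependency ({d}, {g}) outside the universe")

    expression = pd.DataFrame(
        rng.standard_normal((len(genes), len(lines))), index=genes, columns=lines
    )
    dependency = pd.DataFrame(
        rng.standard_normal((len(genes), len(lines))), index=genes, columns=lines
    )
    sensitivity = pd.DataFrame(
        rng.standard_normal((len(drugs), len(lines))), index=drugs, columns=lines
    )

    slope = cfg.planted_effect_size / QUARTILE_SPAN
    sign = -1.0 if cfg.sensitivity_metric is SensitivityMetric.log_fold_change else 1.0
    for drug, gene in planted_dependencies:
        if covariate in ("expression", "both"):
            sensitivity.loc[drug] += sign * slope * expression.loc[gene]
        if covariate in ("dependency", "both"):
            sensitivity.loc[drug] += sign * slope * dependency.loc[gene]

    panel = CellLinePanel(
        expression=expression,
        dependency=dependency,
        sensitivity=sensitivity,
        sensitivity_metric=cfg.sensitivity_metric,
    )
    return panel, sorted(set(planted_dependencies))


# ---------------------------------------------------------------------------
# mutation matrix and evidence index


def gen_mutation_matrix(cfg: GeneratorConfig) -> MutationMatrix:
    """Independent Bernoulli calls per (sample, gene) at configured rates."""
    rng = cfg.rng("mutation")
    genes = cfg.gene_names
    freqs = np.array(
        [cfg.per_gene_mutation_freq.get(g, cfg.default_mutation_freq) for g in genes]
    )
    calls = (rng.random((cfg.n_tumor_samples, len(genes))) < freqs).astype(int)
    samples = [f"SAMP{i:05d}" for i in range(1, cfg.n_tumor_samples + 1)]
    return MutationMatrix(calls=pd.DataFrame(calls, index=samples, columns=genes))


def gen_evidence_index(cfg: GeneratorConfig) -> EvidenceIndex:
    """Per-gene trial-evidence and off-label flags at configured rates."""
    rng = cfg.rng("evidence")
    entries = []
    for g in cfg.gene_names:
        entries.append(
            EvidenceEntry(
                gene=g,
                has_trial_evidence=bool(rng.random() < cfg.p_trial_evidence),
                known_off_label=bool(rng.random() < cfg.p_known_off_label),
            )
        )
    return EvidenceIndex.from_entries(entries)
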