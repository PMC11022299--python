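"""Rule-based functional annotation of somatic variants.

Variants are labelled gain-of-function (GOF), loss-of-function (LOF) or
unknown by a fixed first-match-wins rule cascade, with expert judgement
injected as data: a curated-override table that always wins, and editable
oncogene / kinase / hotspot lists.  Every annotation records the rule that
fired, so a reviewer can audit any call.

Also provides TMB dichotomisation (high at >= 10 mut/Mb, the checkpoint-
inhibitor approval convention) and cohort composition summaries.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from repurpose.errors import ConfigError, TableValidationError
from repurpose.tables import MutationType, PatientReport, VariantCall
from repurpose.validation import round_half_up


class FunctionalClass(str, enum.Enum):
    GOF = "GOF"
    LOF = "LOF"
    unknown = "unknown"


class Pathogenicity(str, enum.Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    possibly_pathogenic = "possibly_pathogenic"
    likely_benign = "likely_benign"


@dataclass(frozen=True)
class FunctionalAnnotation:
    variant: VariantCall
    functional_class: FunctionalClass
    pathogenicity: Pathogenicity
    rule_fired: str
    overridden: bool = False


# Editable default gene lists and hotspots.  These are convenience
# fixtures for synthetic cohorts and quick starts, not curated claims;
# real analyses should load a reviewed knowledge base.
DEFAULT_ONCOGENES = frozenset(
    {
        "KRAS", "NRAS", "HRAS", "BRAF", "PIK3CA", "EGFR", "ERBB2", "ERBB3",
        "KIT", "MET", "ALK", "ROS1", "RET", "MYC", "CCND1", "CCND3", "CCNE1",
        "CDK4", "CDK6", "CDK8", "CDK12", "FGFR1", "FGFR2", "FGFR3", "FLT3",
        "FLT4", "AURKA", "MDM2", "AR", "RARA", "MPL", "ETV4", "ERG",
    }
)
DEFAULT_KINASE_GENES = frozenset(
    {
        "BRAF", "RAF1", "EGFR", "ERBB2", "ERBB3", "KIT", "MET", "ALK",
        "ROS1", "RET", "CDK4", "CDK6", "CDK8", "CDK12", "FGFR1", "FGFR2",
        "FGFR3", "FLT3", "FLT4", "AURKA", "MAP2K1", "PIK3CA", "PIK3C2G",
        "EPHA7",
    }
)
DEFAULT_HOTSPOTS = frozenset(
    {
        ("KRAS", "G12D"), ("KRAS", "G12V"), ("KRAS", "G12C"), ("KRAS", "G13D"),
        ("KRAS", "Q61H"), ("NRAS", "Q61K"), ("NRAS", "Q61R"),
        ("BRAF", "V600E"), ("BRAF", "V600K"),
        ("PIK3CA", "E542K"), ("PIK3CA", "E545K"), ("PIK3CA", "H1047R"),
        ("EGFR", "L858R"), ("KIT", "D816V"), ("AR", "H875Y"),
    }
)

#: FATHMM weighted cancer scores at or below this value are treated as
#: pathogenic (negative scores indicate a deleterious prediction).
DEFAULT_FATHMM_CUTOFF = -0.75


@dataclass
class KnowledgeBase:
    """Gene lists, hotspot set and curated overrides driving the cascade.

    ``curated_overrides`` maps (gene, protein_change) to a pre-made call;
    it models expert manual review and takes precedence over every rule.
    """

    oncogenes: frozenset[str] = DEFAULT_ONCOGENES
    kinase_genes: frozenset[str] = DEFAULT_KINASE_GENES
    hotspot_changes: frozenset[tuple[str, str]] = DEFAULT_HOTSPOTS
    curated_overrides: dict[tuple[str, Optional[str]], tuple[FunctionalClass, Pathogenicity]] = field(
        default_factory=dict
    )
    fathmm_pathogenic_cutoff: float = DEFAULT_FATHMM_CUTOFF

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KnowledgeBase":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        overrides = {}
        for item in raw.get("curated_overrides", []):
            key = (item["gene"], item.get("protein_change"))
            overrides[key] = (
                FunctionalClass(item["functional_class"]),
                Pathogenicity(item["pathogenicity"]),
            )
        return cls(
            oncogenes=frozenset(raw.get("oncogenes", DEFAULT_ONCOGENES)),
            kinase_genes=frozenset(raw.get("kinase_genes", DEFAULT_KINASE_GENES)),
            hotspot_changes=frozenset(
                (h["gene"], h["protein_change"]) for h in raw.get("hotspots", [])
            )
            if "hotspots" in raw
            else DEFAULT_HOTSPOTS,
            curated_overrides=overrides,
            fathmm_pathogenic_cutoff=float(
                raw.get("fathmm_pathogenic_cutoff", DEFAULT_FATHMM_CUTOFF)
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "oncogenes": sorted(self.oncogenes),
            "kinase_genes": sorted(self.kinase_genes),
            "hotspots": [
                {"gene": g, "protein_change": c}
                for g, c in sorted(self.hotspot_changes)
            ],
            "curated_overrides": [
                {
                    "gene": g,
                    "protein_change": c,
                    "functional_class": fc.value,
                    "pathogenicity": p.value,
                }
                for (g, c), (fc, p) in sorted(
                    self.curated_overrides.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")
                )
            ],
            "fathmm_pathogenic_cutoff": self.fathmm_pathogenic_cutoff,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


_LOF_TYPES = {MutationType.truncating, MutationType.deletion, MutationType.splice}


def classify_variant(variant: VariantCall, kb: KnowledgeBase) -> FunctionalAnnotation:
    """First-match-wins rule cascade; total over valid variants.

    Order: curated override; amplification -> GOF; truncating-class ->
    LOF; oncogene/kinase fusion -> GOF; oncogene hotspot nsSNV -> GOF;
    kinase nsSNV with pathogenic FATHMM -> GOF (possibly pathogenic);
    otherwise unknown / likely benign.
    """
    key = (variant.gene, variant.protein_change)
    if key in kb.curated_overrides:
        fc, path = kb.curated_overrides[key]
        return FunctionalAnnotation(
            variant, fc, path, rule_fired="curated_override", overridden=True
        )

    if variant.mutation_type is MutationType.amplification:
        return FunctionalAnnotation(
            variant, FunctionalClass.GOF, Pathogenicity.likely_pathogenic,
            rule_fired="amplification_gof",
        )

    if variant.mutation_type in _LOF_TYPES:
        return FunctionalAnnotation(
            variant, FunctionalClass.LOF, Pathogenicity.likely_pathogenic,
            rule_fired="truncating_lof",
        )

    if variant.mutation_type is MutationType.fusion:
        partners = {variant.gene, variant.partner_gene}
        if partners & (kb.oncogenes | kb.kinase_genes):
            return FunctionalAnnotation(
                variant, FunctionalClass.GOF, Pathogenicity.possibly_pathogenic,
                rule_fired="oncogenic_fusion",
            )
        return FunctionalAnnotation(
            variant, FunctionalClass.unknown, Pathogenicity.likely_benign,
            rule_fired="unrecognised_fusion",
        )

    if variant.mutation_type is MutationType.nsSNV:
        if (
            variant.gene in kb.oncogenes
            and variant.protein_change is not None
            and (variant.gene, variant.protein_change) in kb.hotspot_changes
        ):
            return FunctionalAnnotation(
                variant, FunctionalClass.GOF, Pathogenicity.pathogenic,
                rule_fired="oncogene_hotspot",
            )
        if (
            variant.gene in kb.kinase_genes
            and variant.fathmm_score is not None
            and variant.fathmm_score <= kb.fathmm_pathogenic_cutoff
        ):
            return FunctionalAnnotation(
                variant, FunctionalClass.GOF, Pathogenicity.possibly_pathogenic,
                rule_fired="kinase_fathmm",
            )

    return FunctionalAnnotation(
        variant, FunctionalClass.unknown, Pathogenicity.likely_benign,
        rule_fired="no_rule_matched",
    )


def classify_cohort(
    reports: Sequence[PatientReport], kb: KnowledgeBase
) -> list[FunctionalAnnotation]:
    return [classify_variant(v, kb) for r in reports for v in r.variants]


def dichotomize_tmb(tmb_mut_per_mb: float) -> str:
    """'high' at TMB >= 10 mut/Mb, else 'low'."""
    if tmb_mut_per_mb < 0:
        raise TableValidationError("TMB must be non-negative")
    return "high" if tmb_mut_per_mb >= 10.0 else "low"


def composition_percentages(counts: Mapping[object, int], ndigits: int = 1) -> dict[object, float]:
    """Percent share per key, round-half-up to ``ndigits`` decimals."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round_half_up(100.0 * v / total, ndigits) for k, v in counts.items()}


@dataclass
class GofSummary:
    """Composition of the GOF fraction of a cohort."""

    n_variants: int
    n_gof: int
    by_type: dict[str, int]
    by_type_pct: dict[str, float]
    by_gene: dict[str, int]
    by_gene_pct: dict[str, float]

    @property
    def gof_pct(self) -> float:
        if self.n_variants == 0:
            return 0.0
        return round_half_up(100.0 * self.n_gof / self.n_variants, 1)


def summarize_gof(
    reports: Sequence[PatientReport],
    annotations: Sequence[FunctionalAnnotation],
) -> GofSummary:
    """Counts and percentages of GOF variants by mutation type and gene.

    Fusions are keyed by "GENE-PARTNER" so distinct fusion pairs are
    distinguishable in the per-gene breakdown.
    """
    n_variants = sum(len(r.variants) for r in reports)
    if len(annotations) != n_variants:
        raise ConfigError("annotations must cover every variant in the cohort")
    gof = [a for a in annotations if a.functional_class is FunctionalClass.GOF]
    by_type = Counter(a.variant.mutation_type.value for a in gof)
    by_gene: Counter = Counter()
    for a in gof:
        v = a.variant
        key = f"{v.gene}-{v.partner_gene}" if v.partner_gene else v.gene
        by_gene[key] += 1
    return GofSummary(
        n_variants=n_variants,
        n_gof=len(gof),
        by_type=dict(by_type),
        by_type_pct=composition_percentages(by_type),
        by_gene=dict(by_gene),
        by_gene_pct=composition_percentages(by_gene),
    )
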