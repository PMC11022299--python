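"""Typed data model and TSV/CSV/JSON readers and writers.

All downstream stages consume the types defined here.  Conventions:

* gene identity is an HGNC-style uppercase symbol; every join in the
  pipeline is symbol-keyed (a protein-accession -> symbol mapping, when
  needed, is supplied by the user as an input table, never computed here);
* missing numeric fields are empty cells on disk, never sentinel numbers;
* enum-valued fields are normalised case-insensitively on read.
"""

from __future__ import annotations

import enum
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pydantic
from pydantic import BaseModel, Field

from repurpose.errors import TableFormatError, TableValidationError

# ---------------------------------------------------------------------------
# enums


class Modality(str, enum.Enum):
    small_molecule = "small_molecule"
    other = "other"


class MutationType(str, enum.Enum):
    nsSNV = "nsSNV"
    amplification = "amplification"
    fusion = "fusion"
    deletion = "deletion"
    truncating = "truncating"
    splice = "splice"
    other = "other"


class MsiStatus(str, enum.Enum):
    high = "high"
    low = "low"
    unknown = "unknown"


class SensitivityMetric(str, enum.Enum):
    log_fold_change = "log_fold_change"
    auc = "auc"


def _normalize_enum(cls: type[enum.Enum], raw: object, field_name: str) -> enum.Enum:
    """Case-insensitive enum lookup; idempotent on already-valid members."""
    if isinstance(raw, cls):
        return raw
    text = str(raw).strip()
    for member in cls:
        if member.value.lower() == text.lower():
            return member
    allowed = ", ".join(m.value for m in cls)
    raise TableValidationError(
        f"unknown {field_name} {raw!r}; allowed values: {allowed}"
    )


# ---------------------------------------------------------------------------
# record types


class ProbeRecord(BaseModel):
    """One compound-target pair from the chemical-probe score database.

    ``global_score`` is the database's composite potency/selectivity score in
    [0, 1]; ``rank_in_target`` orders compounds within a target gene
    (1 = best probe for that gene).
    """

    compound_id: str
    target_gene: str
    target_accession: Optional[str] = None
    global_score: float = Field(ge=0.0, le=1.0)
    rank_in_target: Optional[int] = Field(default=None, ge=1)

    model_config = pydantic.ConfigDict(frozen=True)


class FDALabelEntry(BaseModel):
    """An approved drug and its labelled target gene (gold-standard unit)."""

    drug_id: str
    target_gene: str
    modality: Modality = Modality.small_molecule
    biomarker_linked: bool = True

    model_config = pydantic.ConfigDict(frozen=True)

    @pydantic.field_validator("modality", mode="before")
    @classmethod
    def _norm_modality(cls, v: object) -> object:
        if isinstance(v, str):
            return _normalize_enum(Modality, v, "modality")
        return v


class VariantCall(BaseModel):
    """One somatic aberration from an NGS panel report.

    ``vaf`` respects the panel calling floor of 0.05 (variants below a 5 %
    variant-allele-frequency cut-off are not reported by the panels this
    models).  Fusion records must carry ``partner_gene``.
    """

    patient_id: str
    gene: str
    protein_change: Optional[str] = None
    mutation_type: MutationType
    vaf: Optional[float] = Field(default=None, ge=0.05, le=1.0)
    copy_number: Optional[float] = Field(default=None, ge=0.0)
    fathmm_score: Optional[float] = None
    partner_gene: Optional[str] = None

    model_config = pydantic.ConfigDict(frozen=True)

    @pydantic.field_validator("mutation_type", mode="before")
    @classmethod
    def _norm_type(cls, v: object) -> object:
        if isinstance(v, str):
            return _normalize_enum(MutationType, v, "mutation_type")
        return v

    @pydantic.model_validator(mode="after")
    def _check_fusion_partner(self) -> "VariantCall":
        if self.mutation_type is MutationType.fusion and not self.partner_gene:
            raise ValueError(
                f"fusion record for {self.gene} ({self.patient_id}) "
                "must carry partner_gene"
            )
        return self


class PatientReport(BaseModel):
    """All variants of one patient plus report-level biomarkers.

    TMB is non-synonymous mutations per megabase; MSI status is a
    passthrough field from the panel, never recomputed.
    """

    patient_id: str
    variants: list[VariantCall] = Field(default_factory=list)
    tmb_mut_per_mb: Optional[float] = Field(default=None, ge=0.0)
    msi_status: MsiStatus = MsiStatus.unknown

    @pydantic.field_validator("msi_status", mode="before")
    @classmethod
    def _norm_msi(cls, v: object) -> object:
        if isinstance(v, str):
            return _normalize_enum(MsiStatus, v, "msi_status")
        return v

    @pydantic.field_validator("tmb_mut_per_mb")
    @classmethod
    def _finite_tmb(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not math.isfinite(v):
            raise ValueError("tmb_mut_per_mb must be finite")
        return v


class EvidenceEntry(BaseModel):
    """Trial-evidence flags for one gene (clinical-trial index stand-in)."""

    gene: str
    has_trial_evidence: bool = False
    known_off_label: bool = False

    model_config = pydantic.ConfigDict(frozen=True)


class EvidenceIndex(BaseModel):
    """Gene -> trial-evidence flags, one entry per gene."""

    entries: dict[str, EvidenceEntry] = Field(default_factory=dict)

    @classmethod
    def from_entries(cls, entries: Iterable[EvidenceEntry]) -> "EvidenceIndex":
        out: dict[str, EvidenceEntry] = {}
        for e in entries:
            if e.gene in out:
                raise TableValidationError(f"duplicate evidence entry for {e.gene}")
            out[e.gene] = e
        return cls(entries=out)

    def lookup(self, gene: str) -> EvidenceEntry:
        """Flags for ``gene``; absent genes read as all-false (no evidence)."""
        return self.entries.get(gene, EvidenceEntry(gene=gene))


@dataclass
class CellLinePanel:
    """Aligned expression / CRISPR-dependency / drug-sensitivity matrices.

    ``expression`` and ``dependency`` are gene x cell-line, ``sensitivity``
    is drug x cell-line; all three share one cell-line ordering.  In the
    ``log_fold_change`` convention lower sensitivity values mean a more
    sensitive line.
    """

    expression: pd.DataFrame
    dependency: pd.DataFrame
    sensitivity: pd.DataFrame
    sensitivity_metric: SensitivityMetric = SensitivityMetric.log_fold_change

    def __post_init__(self) -> None:
        if isinstance(self.sensitivity_metric, str):
            self.sensitivity_metric = _normalize_enum(  # type: ignore[assignment]
                SensitivityMetric, self.sensitivity_metric, "sensitivity_metric"
            )
        cols = list(self.expression.columns)
        for name, m in (("dependency", self.dependency), ("sensitivity", self.sensitivity)):
            if list(m.columns) != cols:
                raise TableValidationError(
                    f"{name} matrix cell-line ordering differs from expression"
                )
        for name, m in (
            ("expression", self.expression),
            ("dependency", self.dependency),
            ("sensitivity", self.sensitivity),
        ):
            if m.shape[1] and m.isna().all(axis=0).any():
                bad = m.columns[m.isna().all(axis=0)][0]
                raise TableValidationError(
                    f"{name} matrix column {bad!r} is entirely missing"
                )

    @property
    def cell_lines(self) -> list[str]:
        return list(self.expression.columns)


@dataclass
class MutationMatrix:
    """Binary sample x gene somatic-call matrix (pan-cancer extract)."""

    calls: pd.DataFrame  # index = samples, columns = genes, values in {0, 1}

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if vals.size and not ((vals == 0) | (vals == 1)).all():
            raise TableValidationError("mutation matrix calls must be 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def genes(self) -> list[str]:
        return list(self.calls.columns)


# ---------------------------------------------------------------------------
# tabular IO

_SEP = {"tsv": "\t", "csv": ","}

PROBE_COLUMNS = ["compound_id", "target_gene", "target_accession", "global_score", "rank_in_target"]
FDA_COLUMNS = ["drug_id", "target_gene", "modality", "biomarker_linked"]
VARIANT_COLUMNS = [
    "patient_id", "gene", "protein_change", "mutation_type",
    "vaf", "copy_number", "fathmm_score", "partner_gene",
]
REPORT_COLUMNS = ["patient_id", "tmb_mut_per_mb", "msi_status"]
EVIDENCE_COLUMNS = ["gene", "has_trial_evidence", "known_off_label"]


def _read_frame(path: str | Path, dialect: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_SEP[dialect], dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"missing required column {col!r} in {path}")
    return df


def _opt_float(raw: str, field_name: str, row: int) -> Optional[float]:
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise TableValidationError(
            f"row {row}: cannot parse {field_name}={raw!r} as a number"
        ) from None


def assign_ranks(records: Sequence[ProbeRecord]) -> list[ProbeRecord]:
    """Recompute ``rank_in_target`` per gene by descending global score.

    Ties break by compound_id lexicographic order so ranks are
    deterministic.  The multiset of compounds per gene is preserved.
    """
    by_gene: dict[str, list[ProbeRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.target_gene, []).append(rec)
    out: list[ProbeRecord] = []
    for gene in by_gene:
        ranked = sorted(by_gene[gene], key=lambda r: (-r.global_score, r.compound_id))
        for i, rec in enumerate(ranked, start=1):
            out.append(rec.model_copy(update={"rank_in_target": i}))
    return out


def read_probe_table(path: str | Path, dialect: str = "tsv") -> list[ProbeRecord]:
    """Read a probe-score table, validating scores and recomputing ranks.

    Ranks are always recomputed from the scores (descending, stable
    tie-break by compound id) so that the in-memory table satisfies the
    per-gene rank invariant regardless of what the file declared.
    """
    df = _read_frame(path, dialect, ["compound_id", "target_gene", "global_score"])
    records: list[ProbeRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        d = row._asdict()
        score = _opt_float(d["global_score"], "global_score", i)
        if score is None:
            raise TableValidationError(f"row {i}: global_score is required")
        if not 0.0 <= score <= 1.0:
            raise TableValidationError(
                f"row {i}: global_score {score} outside [0, 1]"
            )
        key = (d["compound_id"], d["target_gene"])
        if key in seen:
            raise TableValidationError(f"row {i}: duplicate (compound, gene) pair {key}")
        seen.add(key)
        records.append(
            ProbeRecord(
                compound_id=d["compound_id"],
                target_gene=d["target_gene"],
                target_accession=d.get("target_accession") or None,
                global_score=score,
            )
        )
    return assign_ranks(records)


def read_fda_labels(path: str | Path, dialect: str = "tsv") -> list[FDALabelEntry]:
    df = _read_frame(path, dialect, ["drug_id", "target_gene"])
    out: list[FDALabelEntry] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        key = (d["drug_id"], d["target_gene"])
        if key in seen:
            raise TableValidationError(f"row {i}: duplicate (drug, gene) label {key}")
        seen.add(key)
        try:
            out.append(
                FDALabelEntry(
                    drug_id=d["drug_id"],
                    target_gene=d["target_gene"],
                    modality=d.get("modality") or Modality.small_molecule,
                    biomarker_linked=_parse_bool(d.get("biomarker_linked", "true"), i),
                )
            )
        except pydantic.ValidationError as exc:
            raise TableValidationError(f"row {i}: {exc}") from None
    return out


def _parse_bool(raw: object, row: int, default: bool = True) -> bool:
    if isinstance(raw, bool):
        return raw
    text = str(raw).strip().lower()
    if text == "":
        return default
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise TableValidationError(f"row {row}: cannot parse boolean {raw!r}")


def read_evidence_index(path: str | Path, dialect: str = "tsv") -> EvidenceIndex:
    df = _read_frame(path, dialect, ["gene"])
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        entries.append(
            EvidenceEntry(
                gene=d["gene"],
                has_trial_evidence=_parse_bool(d.get("has_trial_evidence", ""), i, default=False),
                known_off_label=_parse_bool(d.get("known_off_label", ""), i, default=False),
            )
        )
    return EvidenceIndex.from_entries(entries)


def _variant_from_dict(d: dict, where: str) -> VariantCall:
    try:
        return VariantCall(
            patient_id=d["patient_id"],
            gene=d["gene"],
            protein_change=d.get("protein_change") or None,
            mutation_type=d["mutation_type"],
            vaf=d.get("vaf") if not isinstance(d.get("vaf"), str) else _opt_float(d["vaf"], "vaf", 0),
            copy_number=d.get("copy_number") if not isinstance(d.get("copy_number"), str) else _opt_float(d["copy_number"], "copy_number", 0),
            fathmm_score=d.get("fathmm_score") if not isinstance(d.get("fathmm_score"), str) else _opt_float(d["fathmm_score"], "fathmm_score", 0),
            partner_gene=d.get("partner_gene") or None,
        )
    except (pydantic.ValidationError, TableValidationError) as exc:
        raise TableValidationError(f"{where}: {exc}") from None


def read_patient_reports(path: str | Path, dialect: str = "tsv") -> list[PatientReport]:
    """Read a cohort of patient reports from JSON or TSV/CSV.

    JSON input is a list of objects, one per patient, each with a
    ``variants`` array.  Tabular input is one row per variant with
    report-level fields (tmb, msi) repeated; rows are grouped by
    patient_id in first-appearance order.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        reports: list[PatientReport] = []
        seen: set[str] = set()
        for obj in payload:
            pid = obj["patient_id"]
            if pid in seen:
                raise TableValidationError(f"duplicate patient_id {pid!r}")
            seen.add(pid)
            variants = [
                _variant_from_dict({**v, "patient_id": pid}, f"patient {pid}")
                for v in obj.get("variants", [])
            ]
            try:
                reports.append(
                    PatientReport(
                        patient_id=pid,
                        variants=variants,
                        tmb_mut_per_mb=obj.get("tmb_mut_per_mb"),
                        msi_status=obj.get("msi_status", "unknown"),
                    )
                )
            except pydantic.ValidationError as exc:
                raise TableValidationError(f"patient {pid}: {exc}") from None
        return reports

    df = _read_frame(path, dialect, ["patient_id", "gene", "mutation_type"])
    grouped: dict[str, list[VariantCall]] = {}
    meta: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        pid = d["patient_id"]
        grouped.setdefault(pid, [])
        if d["gene"]:
            grouped[pid].append(_variant_from_dict(d, f"row {i}"))
        prev = meta.setdefault(pid, {})
        for col in ("tmb_mut_per_mb", "msi_status"):
            if d.get(col):
                if col in prev and prev[col] != d[col]:
                    raise TableValidationError(
                        f"row {i}: conflicting {col} for patient {pid!r}"
                    )
                prev[col] = d[col]
    reports = []
    for pid, variants in grouped.items():
        m = meta[pid]
        try:
            reports.append(
                PatientReport(
                    patient_id=pid,
                    variants=variants,
                    tmb_mut_per_mb=_opt_float(m.get("tmb_mut_per_mb", ""), "tmb_mut_per_mb", 0),
                    msi_status=m.get("msi_status", "unknown"),
                )
            )
        except pydantic.ValidationError as exc:
            raise TableValidationError(f"patient {pid}: {exc}") from None
    return reports


def _fmt_cell(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, enum.Enum):
        return v.value
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_table(records: Sequence[BaseModel], path: str | Path, dialect: str = "tsv") -> None:
    """Write records (probe, label, evidence, variant...) as TSV/CSV.

    Round-trip contract: reading the file back yields records equal to the
    validated inputs.  Optional fields that are None become empty cells.
    """
    if records:
        columns = list(type(records[0]).model_fields)
    else:
        columns = []
    sep = _SEP[dialect]
    lines = [sep.join(columns)]
    for rec in records:
        d = rec.model_dump()
        lines.append(sep.join(_fmt_cell(d[c]) for c in columns))
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def write_patient_reports(reports: Sequence[PatientReport], path: str | Path) -> None:
    """Write a cohort as JSON (one object per patient)."""
    payload = []
    for r in reports:
        obj = r.model_dump(mode="json")
        for v in obj["variants"]:
            v.pop("patient_id", None)
            for k in list(v):
                if v[k] is None:
                    del v[k]
        if obj.get("tmb_mut_per_mb") is None:
            obj.pop("tmb_mut_per_mb", None)
        payload.append(obj)
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_matrix(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a matrix TSV: first column = row id, remaining = cell-line ids."""
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_SEP[dialect], index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, dialect: str = "tsv", index_label: str = "id") -> None:
    df.to_csv(path, sep=_SEP[dialect], index_label=index_label)


def read_cell_line_panel(directory: str | Path, metric: str = "log_fold_change") -> CellLinePanel:
    """Read expression.tsv / dependency.tsv / sensitivity.tsv from a directory."""
    d = Path(directory)
    return CellLinePanel(
        expression=read_matrix(d / "expression.tsv"),
        dependency=read_matrix(d / "dependency.tsv"),
        sensitivity=read_matrix(d / "sensitivity.tsv"),
        sensitivity_metric=metric,
    )


def write_cell_line_panel(panel: CellLinePanel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_matrix(panel.expression, d / "expression.tsv", index_label="gene")
    write_matrix(panel.dependency, d / "dependency.tsv", index_label="gene")
    write_matrix(panel.sensitivity, d / "sensitivity.tsv", index_label="drug")
    (d / "metric.txt").write_text(panel.sensitivity_metric.value + "\n")


def read_mutation_matrix(path: str | Path, dialect: str = "tsv") -> MutationMatrix:
    df = read_matrix(path, dialect).astype(int)
    return MutationMatrix(calls=df)


def write_mutation_matrix(mm: MutationMatrix, path: str | Path, dialect: str = "tsv") -> None:
    write_matrix(mm.calls, path, dialect, index_label="sample")


def gof_type_counts(variants: Iterable[VariantCall]) -> Counter:
    """Mutation-type counts, a convenience for composition summaries."""
    return Counter(v.mutation_type for v in variants)
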