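"""Quartile-based functional-concordance screen.

For each candidate drug-gene pair, cell lines are binned into quartiles of
the target's expression (or CRISPR dependency) and drug sensitivity is
compared across bins with a one-way fixed-effects ANOVA, plus Welch t-tests
of quartiles 2-4 against quartile 1 with the usual significance stars.
A monotone sensitivity-covariate relationship is the signature of a
functionally consequential drug-target interaction; a flat profile says the
binding signal has no measurable cellular correlate in the panel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from repurpose.errors import AnalysisError
from repurpose.tables import CellLinePanel


class Covariate(str, enum.Enum):
    expression = "expression"
    dependency = "dependency"


MIN_LINES = 8  # at least two lines per quartile


def quartile_bins(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rank-based quartile labels in {1,2,3,4}, stable under ties.

    Sorted positions split at ceil(n/4), ceil(n/2), ceil(3n/4); ties keep
    input order (stable sort), so the assignment is deterministic and the
    bins partition all values with sizes differing by at most 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise AnalysisError("quartile_bins expects a 1-d vector")
    if np.isnan(arr).any():
        raise AnalysisError("quartile_bins expects non-missing values only")
    n = arr.size
    if n < MIN_LINES:
        raise AnalysisError(f"need >= {MIN_LINES} values for quartiles, got {n}")
    order = np.argsort(arr, kind="stable")
    cuts = [int(np.ceil(n / 4)), int(np.ceil(n / 2)), int(np.ceil(3 * n / 4))]
    bins = np.empty(n, dtype=int)
    positions = np.arange(n)
    labels = 1 + (positions >= cuts[0]).astype(int) \
               + (positions >= cuts[1]).astype(int) \
               + (positions >= cuts[2]).astype(int)
    bins[order] = labels
    return bins


def _groups(sensitivity: np.ndarray, bins: np.ndarray) -> list[np.ndarray]:
    if sensitivity.shape != bins.shape:
        raise AnalysisError("sensitivity and bins must align")
    return [sensitivity[bins == q] for q in (1, 2, 3, 4)]


def anova_by_quartile(
    sensitivity: Sequence[float] | np.ndarray, bins: np.ndarray
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of sensitivity across the 4 quartile bins.

    Returns (F, p) with p from F(3, n-4).  A panel with no between-bin
    variation returns (0, 1) rather than an indeterminate ratio.
    """
    sens = np.asarray(sensitivity, dtype=float)
    groups = _groups(sens, bins)
    if any(g.size < 2 for g in groups):
        raise AnalysisError("every quartile bin needs >= 2 members for ANOVA")
    means = [g.mean() for g in groups]
    if np.ptp(means) == 0.0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def star_code(p: float) -> str:
    """Significance stars: * p<.05, ** p<.01, *** p<.001, **** p<.0001."""
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return "ns"


def ttests_vs_q1(
    sensitivity: Sequence[float] | np.ndarray, bins: np.ndarray
) -> tuple[list[float], list[str]]:
    """Welch t-tests of quartiles 2, 3, 4 each against quartile 1."""
    sens = np.asarray(sensitivity, dtype=float)
    groups = _groups(sens, bins)
    if any(g.size < 2 for g in groups):
        raise AnalysisError("every compared bin needs >= 2 members")
    pvals = []
    for q in (1, 2, 3):
        _, p = stats.ttest_ind(groups[q], groups[0], equal_var=False)
        pvals.append(1.0 if np.isnan(p) else float(p))
    return pvals, [star_code(p) for p in pvals]


@dataclass
class ConcordanceResult:
    drug_id: str
    gene: str
    covariate: Covariate
    n_lines: int
    anova_f: float
    anova_p: float
    quartile_means: tuple[float, float, float, float]
    ttest_p_vs_q1: tuple[float, float, float]
    star_codes: tuple[str, str, str]
    significant: bool


@dataclass
class ScreenSummary:
    """Pair-level rollup of a concordance screen."""

    n_pairs: int
    n_with_data: int
    n_skipped: int
    significant_either: int
    significant_expression_only: int
    significant_dependency_only: int
    significant_both: int

    @property
    def significant_any_fraction(self) -> float:
        if self.n_with_data == 0:
            return 0.0
        return self.significant_either / self.n_with_data


def screen_pair(
    drug_id: str,
    gene: str,
    panel: CellLinePanel,
    covariate: Covariate,
    alpha: float = 0.05,
) -> Optional[ConcordanceResult]:
    """Quartile ANOVA for one (drug, gene) pair on one covariate.

    Returns None when the pair cannot be resolved (drug or gene absent, or
    too few pairwise-complete cell lines).  Missing cells are dropped
    pairwise: a line missing either the covariate or the sensitivity value
    is excluded from this test only.
    """
    cov_matrix = panel.expression if covariate is Covariate.expression else panel.dependency
    if gene not in cov_matrix.index or drug_id not in panel.sensitivity.index:
        return None
    cov = cov_matrix.loc[gene].to_numpy(dtype=float)
    sens = panel.sensitivity.loc[drug_id].to_numpy(dtype=float)
    keep = ~(np.isnan(cov) | np.isnan(sens))
    cov, sens = cov[keep], sens[keep]
    if cov.size < MIN_LINES:
        return None
    bins = quartile_bins(cov)
    if any((bins == q).sum() < 2 for q in (1, 2, 3, 4)):
        return None
    f, p = anova_by_quartile(sens, bins)
    pvals, stars = ttests_vs_q1(sens, bins)
    means = tuple(float(sens[bins == q].mean()) for q in (1, 2, 3, 4))
    return ConcordanceResult(
        drug_id=drug_id,
        gene=gene,
        covariate=covariate,
        n_lines=int(cov.size),
        anova_f=f,
        anova_p=p,
        quartile_means=means,  # type: ignore[arg-type]
        ttest_p_vs_q1=tuple(pvals),  # type: ignore[arg-type]
        star_codes=tuple(stars),  # type: ignore[arg-type]
        significant=bool(p < alpha),
    )


def concordance_screen(
    pairs: Sequence[tuple[str, str]],
    panel: CellLinePanel,
    alpha: float = 0.05,
    adjust: bool = False,
) -> tuple[list[ConcordanceResult], ScreenSummary]:
    """Screen each (drug, gene) pair on both covariates.

    Raw p-values drive the significance calls by default; ``adjust=True``
    applies Benjamini-Hochberg across all computed ANOVA p-values and bases
    ``significant`` on the adjusted values instead.
    """
    if not 0.0 <= alpha <= 1.0:
        raise AnalysisError("alpha must be in [0, 1]")
    results: list[ConcordanceResult] = []
    per_pair: dict[tuple[str, str], dict[Covariate, bool]] = {}
    n_skipped = 0
    for drug_id, gene in pairs:
        got_any = False
        for cov in (Covariate.expression, Covariate.dependency):
            res = screen_pair(drug_id, gene, panel, cov, alpha=alpha)
            if res is None:
                continue
            got_any = True
            results.append(res)
            per_pair.setdefault((drug_id, gene), {})[cov] = res.significant
        if not got_any:
            n_skipped += 1

    if adjust and results:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.anova_p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.anova_p = q
            r.significant = bool(q < alpha)
        per_pair = {}
        for r in results:
            per_pair.setdefault((r.drug_id, r.gene), {})[r.covariate] = r.significant

    expr_only = dep_only = both = either = 0
    for flags in per_pair.values():
        e = flags.get(Covariate.expression, False)
        d = flags.get(Covariate.dependency, False)
        if e or d:
            either += 1
        if e and d:
            both += 1
        elif e:
            expr_only += 1
        elif d:
            dep_only += 1
    summary = ScreenSummary(
        n_pairs=len(pairs),
        n_with_data=len(per_pair),
        n_skipped=n_skipped,
        significant_either=either,
        significant_expression_only=expr_only,
        significant_dependency_only=dep_only,
        significant_both=both,
    )
    return results, summary


def violin_plot(
    drug_id: str,
    gene: str,
    panel: CellLinePanel,
    covariate: Covariate,
    path: str,
) -> None:
    """Violin plot of drug sensitivity by covariate quartile, with stars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = screen_pair(drug_id, gene, panel, covariate)
    if res is None:
        raise AnalysisError(f"pair ({drug_id}, {gene}) not resolvable in the panel")
    cov_matrix = panel.expression if covariate is Covariate.expression else panel.dependency
    cov = cov_matrix.loc[gene].to_numpy(dtype=float)
    sens = panel.sensitivity.loc[drug_id].to_numpy(dtype=float)
    keep = ~(np.isnan(cov) | np.isnan(sens))
    bins = quartile_bins(cov[keep])
    groups = [sens[keep][bins == q] for q in (1, 2, 3, 4)]

    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    ax.violinplot(groups, showmeans=True)
    ax.set_xticks([1, 2, 3, 4], [f"Q{q}" for q in (1, 2, 3, 4)])
    ax.set_xlabel(f"{gene} {covariate.value} quartile")
    ax.set_ylabel(f"{drug_id} sensitivity ({panel.sensitivity_metric.value})")
    top = max(g.max() for g in groups)
    for i, stars in enumerate(res.star_codes, start=2):
        if stars != "ns":
            ax.text(i, top, stars, ha="center", va="bottom")
    ax.set_title(f"ANOVA p = {res.anova_p:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def results_frame(results: Sequence[ConcordanceResult]) -> pd.DataFrame:
    """Wide per-pair table: one row per pair, one p-value column per covariate."""
    rows: dict[tuple[str, str], dict] = {}
    for r in results:
        key = (r.gene, r.drug_id)
        row = rows.setdefault(key, {"gene": r.gene, "drug_id": r.drug_id})
        prefix = r.covariate.value
        row[f"{prefix}_p"] = r.anova_p
        row[f"{prefix}_significant"] = r.significant
    return pd.DataFrame(sorted(rows.values(), key=lambda d: (d["gene"], d["drug_id"])))
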