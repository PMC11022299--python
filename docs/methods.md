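# Methods

## The screening model

The package operationalises off-target drug repurposing as a sequence of
set operations and classical tests over four data sources: a compound ×
target probe-score table, an FDA drug–biomarker label table, per-patient
NGS variant reports, and cell-line molecular/pharmacological panels.

The central assumption is that a probe-quality binding score is an
actionable proxy for therapeutic potential: a drug scoring above an
inclusion threshold τ for a gene is treated as a candidate for tumours
with a GOF aberration in that gene. The gold-standard validation stage
quantifies exactly how far that assumption carries — by asking how well
thresholded scores recover drug–biomarker pairs that regulators have
already approved — and the concordance screen probes its functional side:
whether lines expressing (or depending on) the target more strongly are
also more sensitive to the drug. Binding without cellular concordance is
reported, not suppressed; the screen is exploratory, and a flat profile on
a noisy panel does not falsify a true interaction.

### Drug universe and confusion matrices

All validation statistics are computed within one global universe
*U* = {FDA-approved drugs} ∩ {compounds in the probe table}, so every
per-gene confusion matrix sums to |U| by construction. A conservation test
exploits this invariant: tn is pinned at |U| − tp − fp − fn. Per-gene
metrics are only computed for biomarkers with ≥ `min_therapies` (default
2) distinct labelled drugs; below that the per-gene estimates are too
coarse to be informative. Undefined ratios (tp+fp = 0 for precision,
tp+fn = 0 for sensitivity) are reported as undefined, never as 0, to avoid
penalising genes with no predictions.

Two table-level statistics are deliberately separate from thresholding:
the fraction of gold-standard pairs *indexed at all* in the probe table
(a pair can be present below τ), and the fraction ranked in the per-gene
top ten probes.

### Rule cascade

Variant classification is a total function: first matching rule wins, and
every annotation records `rule_fired`, so downstream tables are auditable.
Expert judgement enters only as data — a curated-override table that
defeats every rule, modelling the manual two-reviewer step of a clinical
workflow without encoding opinions in code. Fusions are called GOF only
when a partner is a known oncogene or kinase; unrecognised fusions stay
unknown. FATHMM is consumed as a number: scores at or below the cutoff
(default −0.75, the usual convention for weighted cancer scores, where
more negative means more deleterious) count as pathogenic support for
kinase-gene missense variants. The cutoff and all gene/hotspot lists are
editable inputs, not claims.

TMB is dichotomised high at ≥ 10 mut/Mb. The boundary side is a
convention choice (the checkpoint-inhibitor approval threshold is quoted
as "10 mut/Mb" without a side); ≥ is used so a report printing exactly
10 is treated as high.

### Triage cascade

Categories are assigned in fixed order — Tier-I excluded → trial-level →
off-label → novel — making them mutually exclusive and exhaustive, which
the tests verify as a partition invariant. A gene absent from the
evidence index is treated as having no evidence (flags false) rather than
an error, since trial indexes are always incomplete. Deduplication keys
on (gene, mutation type) by default: it preserves the clinically relevant
distinction between, say, an amplification and a point mutation of the
same gene, while still collapsing recurrent events across patients.
Gene-only deduplication is available because the coarser semantics are
defensible too; the choice is recorded in the output rather than hidden.

### Quartile ANOVA

Quartile bins are rank-based: sorted positions split at ⌈n/4⌉, ⌈n/2⌉,
⌈3n/4⌉, ties broken by input order via a stable sort, so binning is
deterministic under duplicated covariate values and bin sizes differ by
at most one. The across-bin comparison is a one-way fixed-effects ANOVA
(F on 3, n − 4 df); per-quartile contrasts against Q1 use Welch's
unequal-variance t-test, the safer default when bin variances differ.
Cells missing either the covariate or the sensitivity value are dropped
pairwise, per test. A panel with no between-bin variation returns
(F = 0, p = 1) rather than an indeterminate 0/0. No multiple-testing
correction is applied by default — the screen reports raw p-values as an
exploratory instrument — but Benjamini–Hochberg adjustment is available
behind a flag and replaces the significance calls when enabled.

Significance stars follow the standard legend: \* p < .05, \*\* p < .01,
\*\*\* p < .001, \*\*\*\* p < .0001.

### Repurposable genome

Enumeration keeps, per gene, every FDA-approved compound with score
strictly > τ (0.25), then removes combinations already on an FDA label.
Label exclusion is pair-level by default — a labelled drug remains a
candidate for *other* genes, which is the whole point of off-target
repurposing — with drug-level exclusion behind a flag. The event count is
the full surviving pass-list, not a top-N truncation; display top-N
(default 1) only affects reporting. The high-confidence subset applies a
second strict threshold (default 0.7) and feeds the concordance screen.
The mutation-burden estimate takes the mutation matrix as-is, with no
pathogenicity filtering, and counts samples with ≥ 1 call in any
repurposable gene.

## Synthetic data: what it emulates, and what it does not

Generators draw from per-generator streams seeded as (seed, stream-id),
so adding a call to one generator never perturbs another's output, and a
fixed (seed, config) reproduces every table byte for byte.

Defaults encode the study conditions the pipeline is designed around:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 94 | cohort size of NGS reports |
| `mean_variants_per_report` | 4.2 | Poisson mean of reported variants |
| `p_gof` | 0.454 | share of variants that are GOF |
| `gof_type_mix` | (.583, .356, .033, .028) | amplification / nsSNV / fusion / other among GOF |
| `planted_score_floor` | 0.6 | planted true pairs score U(floor, 1) |
| `decoy_score_mean`, `score_noise_sd` | 0.05, 0.02 | decoy Beta distribution |
| `n_cell_lines` | 200 | panel width |
| `planted_effect_size` | 1.5 | SD shift in sensitivity per covariate quartile |
| `n_tumor_samples`, `default_mutation_freq` | 2922, 0.05 | mutation-matrix shape and rate |
| `tmb_log_mean`, `tmb_log_sd` | 1.1, 0.8 | log-normal TMB (≈ 6–7 % of reports ≥ 10 mut/Mb) |

The GOF type mix is stored normalised; the printed three-decimal shares it
derives from sum to 0.999 by rounding, and the "other" share absorbs the
remainder (0.028).

Decoy probe scores follow a Beta distribution with the configured mean and
standard deviation (a point mass when sd = 0), keeping every score a valid
probe score in [0, 1] and giving the decoy tail mass above any threshold a
closed form the tests check against. Planted sensitivity–covariate effects
are linear in the standard-normal covariate with slope
`planted_effect_size / 0.8475`, where 0.8475 = (E[X|Q4] − E[X|Q1])/3 for a
standard normal — so the *average* sensitivity drop between consecutive
covariate quartiles equals `planted_effect_size` in units of the
unit-variance residual noise. In AUC mode the slope sign flips (higher
AUC = more sensitive).

Deliberately not modelled: mutational signatures and gene–gene linkage,
copy-number segment structure, panel-specific artefacts, pharmacokinetics,
correlated expression/dependency across genes, and batch structure in the
panels. Passing tests therefore demonstrate that the *procedure* is
correct and calibrated under clean planted signals — not that real
databases would yield the same headline rates. Cohort-level figures
(events per cohort, actionable-patient percentage, burden percentage)
depend on database snapshots and cohort composition and are reproduced at
procedure level only.

## Numerical choices

- Display rounding is decimal half-up (2 decimals for metrics, 1 for
  percentages), matching how such tables are conventionally printed;
  full precision is kept internally.
- Threshold comparison is strict `>` at both 0.25 and 0.7 (configurable
  to ≥); ranking ties break lexicographically by compound id so ranks are
  deterministic.
- Missing numeric fields are empty cells on disk, never sentinels; enum
  parsing is case-insensitive and idempotent.
- The variant-allele-frequency floor of 0.05 is enforced at the data
  model, reflecting the 5 % calling cut-off of the panels the reports
  emulate.
- Problem sizes in the test suite and acceptance script (1 000 null pairs
  at 100 lines, 100 power replicates at 200 lines, 10 000-rep permutation
  oracles at n = 40, 10 000-sample mutation matrices) were chosen as the
  smallest sizes at which the binomial/Monte-Carlo error bands in use
  (± 0.02 on rejection rates, 3 SE on proportions) are meaningful.

## Known limitations

- The probe global score is a relative, database-derived quantity; an
  absolute inclusion threshold is inherently arbitrary, and the package
  treats it as a tunable policy, not a discovered constant.
- Binding-score evidence says nothing about achievable exposure,
  resistance mechanisms or toxicity; the output is a triage list for
  expert review, not a recommendation.
- The concordance screen's quartile binning discards within-quartile
  information; it trades power for robustness and comparability across
  pairs.
- Evidence indexes and off-label lists are consumed as given; the package
  does not attempt literature search or novelty verification.
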