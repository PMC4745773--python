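# Methods

This note documents the statistical procedures `stromamark` implements, the
defaults it ships, the design choices made where the design was genuinely
open, and what the synthetic-data generators do and do not emulate.

## Target-decoy acceptance (identification)

Protein-level identifications from each LC-MS run carry an "unused" score —
confidence from peptide evidence not already claimed by higher-ranking
proteins — and a decoy flag from matches against reversed/shuffled
sequences. The false discovery rate at a candidate cutoff *t* is estimated
by the simple target-decoy ratio #decoys(score ≥ *t*) / #targets(score ≥
*t*); `estimate_fdr_threshold` returns the smallest observed score meeting
the requested FDR (default 1%). The doubled-decoy estimator 2·D/(T+D) is a
common alternative; the simple ratio was chosen because it is the
conservative per-run "score cutoff" convention and the difference is
immaterial at the 1% level with the decoy fractions used here.

Acceptance requires a score **strictly above** the run cutoff and at least
2 unique peptides at the configured confidence level, in at least one run
(`min_unique_peptides` and `require_in_n_runs` are configurable). The
confidence level attached to the peptide count is a label on the input
column, not a computation performed here; the default label is 95%.
Degenerate runs without decoys fall back to the minimum observed score with
a warning rather than failing, since their estimated FDR is zero
everywhere. Runs are merged by accession with per-run presence flags and,
when ratio matrices are supplied, a quantified-in-all / some / none
partition.

## iTRAQ enrichment calls (quantitation)

The 8-plex design labels five fibroblast samples on channels 113–117 and
three cancer epithelial lines on 118/119/121; all ratios are reporter-ion
ratios to channel 113, so the reference column is identically 1. Because
channel 113 itself labels a fibroblast sample, its constant ratio is
included in the fibroblast sample vector: dropping it would discard a real
group member, and the group comparison remains valid with one degenerate
observation.

Per run, FC = mean(fibroblast ratios) / mean(cancer ratios) on the raw
scale (matching the "average fold change" reporting convention), while the
two-sample t-test runs on log2 ratios by default — isobaric ratio noise is
multiplicative, and on the log scale the test is also invariant to a
common rescaling of a run. A raw-scale test and the Welch variant are
config switches; the default is the pooled-variance Student test. Proteins
with fewer than two non-missing ratios in either group are unquantifiable
in that run.

The final call is the conjunction rule: fibroblast-enriched iff FC ≥
`fc_min` (default 2) and p < `alpha` (default 0.05) in **every** replicate
run; epithelial-enriched iff FC ≤ 1/`fc_min` and p < `alpha` in every run;
otherwise neither. An accession unquantifiable in any run cannot be called
when `require_all` is set. `average_fc` is the arithmetic mean of per-run
fold changes, always reported on the fibroblast/cancer scale (for
epithelial calls the reciprocal is the more natural magnitude; consumers
can invert).

Optional per-channel median normalization approximates instrument-software
bias correction; it is off by default because the synthetic inputs are
generated ratio-true.

## Localization cascade

Classification is a strict two-tier priority: any secreted-tier evidence —
a component term among {secreted, extracellular region, extracellular
space, extracellular matrix}, a signal-peptide predictor consensus, or a
non-classical-secretion prediction — wins over any membrane-tier term
({plasma membrane, cell membrane, cell junction}); everything else is
intracellular. The tier order is taken literally even when a record carries
contradictory terms from both tiers. Term dictionaries ship as a versioned
YAML file and match case-insensitively on whole terms; the upstream
predictors themselves are out of scope (their consensus arrives as two
booleans).

Exosome-catalog membership (the count of extracellular-vesicle experiments
containing the protein) is reported with each call and summarized as an
overlap fraction overall and per class, but never reclassifies: vesicle
compendia contain many canonical intracellular proteins, and the class is
meant to reflect annotation/predictor evidence only. Summary percentages
are integer-rounded (round(100·count/total)), so they may not sum to 100.

## Vote-count screen

A gene is cancer-up when at least `up_min` independent microarray analyses
called it significantly up and at most `down_max` called it down; the
mirrored rule gives cancer-down. The default `up_min` is **15 inclusive**:
the bundled 28-gene reference table contains genes with exactly 15
concordant analyses in their called direction (FKBP10, CLEC11A up; COTL1,
FLNC down), so the inclusive reading is the one consistent with the data
even though "more than 15" could be read as exclusive. Dashes in vote
columns parse as 0. At the defaults the reference table splits 20 up / 8
down with no unclassified gene.

## Biomarker evaluation

All of these are implemented from first principles (the module's role is
to make the formulas auditable); `lifelines`, `scikit-learn` and `scipy`
serve as independent cross-checks in the test suite.

* **Kaplan-Meier**: the product-limit estimator with standard risk-set
  bookkeeping; censorings at an event time leave the risk set after the
  events (Mantel-Cox tie convention). S(0)=1, right-continuous,
  non-increasing.
* **Log-rank**: the unweighted Mantel-Cox statistic. For k groups the
  statistic is (O−E)ᵀ V⁻¹ (O−E) over k−1 components with the hypergeometric
  covariance, on k−1 degrees of freedom; k=2 reduces to Σ(O−E)²/ΣV on 1 df.
  A singular covariance (e.g. a group exhausted early) falls back to the
  pseudo-inverse.
* **Median dichotomization**: values equal to the median go to the
  lower group (deterministic; `exclude` available). With ties the group
  sizes can differ by up to 2k−1 for k median ties; callers comparing
  balanced groups should check the tie count.
* **IHC scoring**: a sample-region's intensity is the mean over its images
  of IOD/area; positivity is **strictly above** the cutoff (default 0.043).
  The printed cutoff was originally chosen manually between ranked samples,
  so behaviour exactly at the boundary is unobservable; strict inequality
  is the documented choice. The score is invariant to a common rescaling of
  IOD and area.
* **Fisher / chi-square**: the two-sided Fisher p sums hypergeometric
  probabilities of all tables (given margins) no more likely than the
  observed one, with a 1e-7 relative guard against floating-point ties —
  the same convention as `scipy.stats.fisher_exact`. `association_test`
  routes to Fisher when any expected cell is below 5, else to the
  uncorrected Pearson chi-square.
* **ROC**: every observed concentration is swept as a threshold (call
  positive when concentration ≥ threshold), cases assumed
  higher-concentration; an AUC below 0.5 triggers an orientation warning
  rather than a silent flip. The trapezoidal AUC equals the Mann-Whitney
  pairwise statistic with half credit for ties. The optimal cutoff
  maximizes sensitivity + specificity (Youden's J), ties broken toward the
  lower cutoff so the rule is deterministic.

## Synthetic-data model

Every generator is a pure function of a `SyntheticConfig`; substreams are
derived per stage so stages can be regenerated independently under one
seed. Each generator also emits its truth table.

* **Identifications** (per run): target scores are log-normal around the
  planted cutoff τ (defaults 2 / 1.62 / 2.01 for the three runs); decoys
  are drawn mostly well below τ, with ⌊0.01·A⌋ contamination decoys above τ
  (A = targets above) and a clump of duplicated decoy scores immediately
  below τ. The duplication makes the decoy/target ratio jump by ≥ 2 decoys
  at the first candidate below τ, so the 1%-FDR crossing is planted sharply
  at τ and the estimator must recover it within one candidate-score step.
* **Ratios**: log-normal noise at a configurable CV (default 0.2) around
  class means — cancer channels at 1/`fc_effect` for fibroblast-enriched
  proteins and at `fc_effect` for epithelial-enriched ones (ratios are
  relative to a fibroblast reference). Defaults plant 116 + 44 enriched
  among 1000 proteins at `fc_effect` 8 across 3 runs.
* **Annotations**: classes drawn at 0.53/0.16/0.31; evidence is generated
  class-consistently (secreted proteins get exactly one secreted-tier
  source, possibly plus a contradictory membrane term to exercise the
  priority rule), so the classifier round-trips exactly. Exosome membership
  is Bernoulli(0.95) times a positive count.
* **Votes**: planted up genes draw n_up in [15, n_total−1] and n_down in
  {0, 1} (mirrored for down); null genes draw modest binomial votes.
* **Plasma**: normal concentrations truncated at zero, 42 cases at mean
  61.6 ng/mL and 48 controls at 45.0 ng/mL. The standard deviations are
  free parameters of the model; the defaults σ_control = 8.0 and σ_case =
  11.0 give a closed-form two-normal AUC Φ(Δ/√(σ₁²+σ₂²)) ≈ 0.889, i.e. the
  regime of a usefully discriminating but imperfect circulating marker.
* **Survival**: exponential event times with a planted hazard ratio
  (default 2) between marker-high and marker-low halves of a 90-subject
  cohort, baseline median 51 months, uniform administrative censoring up to
  85 months.
* **IHC**: 1–3 images per sample-region with the per-region mean intensity
  planted strictly on one side of the 0.043 cutoff.

What the generators do **not** emulate: spectrum-level effects (isotope
impurity, ratio compression toward 1 in dense backgrounds), correlated
missingness across channels, batch structure between runs, non-normal
heavy-tailed plasma distributions, informative censoring, or annotation
noise (evidence inconsistent with the true compartment). Passing tests
therefore demonstrate the correctness of the decision rules and statistics
under the stated noise models, not robustness to those real-data artefacts.

## Problem sizes and numerics

The test suite and the acceptance checks run the generators at the study's
design scale (1000 proteins × 3 runs × 8 channels; 90 plasma samples; a
90-subject cohort) and repeat stochastic checks over 20–30 seeds, which
keeps the full suite in the seconds range. Numerical choices worth noting:
zero-variance t-tests resolve by limits (identical groups → p = 1,
separated constants → p = 0); the FDR scan treats a zero-target candidate
as infinite FDR; all-censored groups yield an empty KM table representing
S ≡ 1; and the ROC always contains the (0,0) and (1,1) endpoints so the
trapezoid rule is well defined for a single observed threshold.

## Known limitations

* The enrichment t-test with the constant reference ratio in the
  fibroblast vector slightly deflates that group's variance estimate; with
  5-vs-3 channels and the conjunction-across-runs rule this does not
  measurably inflate null calls (the null-control test bounds the
  per-direction rate at α³ scale), but single-run p values should not be
  interpreted strictly.
* The vote screen inherits whatever multiple-testing behaviour the source
  analyses had; vote counting is a robustness heuristic, not a calibrated
  meta-analysis.
* `association_test` implements only the default uncorrected chi-square as
  the large-sample branch; continuity-corrected and exact mid-p variants
  are out of scope.
* The k-group log-rank assumes large-sample chi-square behaviour; for very
  small strata a permutation version would be preferable.
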