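# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the experimental design left
choices open.

## The annotation task and its data model

One study individual is a `CohortRecord` with ten annotation variables —
five continuous (age [years], ALAT [μkatal/l], alcohol [g/day], hs-CRP
[mg/l], LDL cholesterol [mmol/l]) and five nominal (beta-blocker,
diabetes, hypertension, sex, smoking status) — plus the hidden outcome:
MRI liver-fat fraction (%) and the steatosis label (1 iff moderate-to-
severe).  Steatosis classes follow the liver-fat thresholds: none ≤ 5 %,
mild 5–14 %, moderate-to-severe ≥ 14 %.  The boundary value 5.0 % is
classed as *none* and 14.0 % as *moderate-to-severe*.

Triplets are built from 45 + 45 records sampled uniformly (mild cases are
excluded *before* sampling), split into six groups of 15: groups 1–3
healthy, 4–6 steatosis.  Members are matched by number; triplets 1–15 use
groups (1, 2, 6) and hide a healthy record, triplets 16–30 use (3, 4, 5)
and hide a steatosis record, so the 30 tasks are balanced 15/15 on the
true label.  Which record of the same-class pair becomes the hidden B is
not determined by the design; the default assigns the lower-numbered group
(1 or 4) to the visible anchor slot, and the choice is a constructor flag.
Presentation order equals construction order by default, with a seedable
shuffle available: whether the original experiment randomised order per
participant is unknown, and a fixed order keeps runs comparable.

## The similarity-based machine annotator

HEOM aggregates per-variable distances as √(Σ d²) — the standard
definition of the metric; nominal variables contribute 0/1 overlap,
continuous ones |Δ|/(max − min) with the range fitted on a stated
reference set (by convention the 90 records of the 30 triplets).
Numerical choices:

- continuous differences are clipped to [0, 1] so a query value outside
  the reference range (possible with synthetic data) cannot dominate —
  each variable contributes at most 1, keeping the √10 bound;
- a zero-width range yields distance 0 for that variable (a constant
  variable carries no information);
- missing values are rejected at I/O rather than imputed — the analysis
  assumes complete grids;
- equal anchor distances resolve deterministically to C with a logged
  warning (reproducibility over coin flips), and uncertainty is maximal
  (1) when both distances are zero.

The uncertainty score is the ratio of the smaller to the larger anchor
distance, in [0, 1].  Its 4-level form is round-half-up(3u) — so u = 0.5
maps to level 2, "rather uncertain" — and its binary form flags *certain*
iff u < τ_ASBA with τ_ASBA = 0.5, the prior of the balanced two-class
problem.

## Agreement and correctness metrics

Per-triplet vote tallies give agrm(t) = max{votes_A, votes_C}/n ∈ [0.5, 1].
Two different discretisation rules coexist in the upstream analysis and
both are implemented as printed:

- the *agreement flag* compares agrm rounded to two decimals against τ
  truncated to two decimals (0.66, 0.75).  This is the only reading that
  reproduces every published flag simultaneously — 19/29 ≈ 0.655 is
  flagged at τ = 2/3 while 21/29 ≈ 0.724 is not flagged at τ = 3/4 —
  which a plain agrm ≥ τ comparison cannot do;
- the *triplet score binarisation* (for correctness and stated-U sums)
  uses score ≥ floor(n·τ) exactly.

The inconsistency is upstream, not ours; both rules are exposed separately.
Counts are reconstructed from printed 2-decimal vote ratios as
round-half-up(ratio·n), with the A/C pair required to sum to n.

Krippendorff's α (nominal scale) is computed from per-item vote counts,
which are sufficient statistics for complete binary ratings:
α = 1 − D_o/D_e with D_o = (1/N)Σ_u 2·a_u·c_u/(m_u − 1) and
D_e = 2·n_A·n_C/(N(N−1)).  The tests verify this closed form against an
independent brute-force pair-enumeration oracle on small random matrices.
The 0.667/0.800 reliability guideline is exposed as a label.  No bootstrap
CI is provided.

Stated uncertainty is encoded 0–3 (very certain … very uncertain) and
binarised at ≥ 2.  The binary-uncertainty × correctness 2×2 table is
tested with Pearson χ² (no continuity correction, 1 df).

## EDA processing

Recordings are segmented into consecutive half-open windows [t_i, t_i+d_i)
from the experiment start, using the recorded per-task durations.  Each
segment is summarised as the mean of readings at 10-second offsets from
the segment start; a segment shorter than 10 s contributes its single
offset-0 reading.  Readings use sample-and-hold (the last recorded sample
at or before the offset): the sampling interval is part of the upstream
design, the interpolation rule is not, and sample-and-hold makes the
summary invariant to denser raw recordings.  Experiment start/end markers
are explicit inputs.  No tonic/phasic decomposition or artifact removal is
performed (vendor software handles that upstream of this package).

## Mixed-effects association suite

All associations are modelled with a per-annotator random intercept,
because both duration and EDA carry strong individual traits.  Continuous
outcomes (duration, EDA mean) use a linear mixed model fitted by REML.
The optimizer is Powell (Nelder–Mead fallback): in this data regime the
random-intercept variance frequently sits at the zero boundary, where the
gradient-based default can stall on a degenerate profile; at that boundary
the fit coincides with OLS, which the tests check to 1e-6.

The binary correctness outcome uses a binomial mixed GLM fitted by
variational Bayes, with Wald-style intervals and p-values from the
posterior mean and sd of the fixed effect, reported on the odds-ratio
scale.  This is the package's fit-method choice: the upstream analysis
does not name a family or software, so logistic-family coefficients are
comparable in sign and significance, not digit for digit.

Significance is read at p < 0.05 with no multiple-testing correction,
matching the upstream convention.  The fitted grid: stated-U→duration,
EDA→duration, stated-U→EDA (unadjusted); triplet-ordinal→duration and →EDA;
correctness→duration, correctness→EDA, stated-U→correctness (each adjusted
for triplet ID); and stated-U→duration/EDA adjusted for triplet ID.  The
first three triplets (acclimatization phase) are excluded by default
(`skip_first = 3`).  EDA rows are skipped with a logged notice when events
carry no EDA means.

## Synthetic-data generators

The generators emulate the *structure* of the study inputs, not the
restricted cohort's marginals:

- **Cohort** (default n = 852, class proportions 501/238/113 ≈
  0.59/0.28/0.13): liver fat drawn per class (uniform within none/mild,
  14 + Exponential(8) for moderate-to-severe); the ten risk factors drawn
  from class-shifted distributions with plausible clinical magnitudes
  (e.g. age ~ N(50, 12²) healthy vs N(58, 12²) steatosis, truncated to
  [20, 90]; log-normal ALAT and CRP; Bernoulli comorbidities with higher
  rates in the steatosis class).  All parameters are invented,
  config-driven defaults — their only job is to give the nearest-neighbour
  annotator a recoverable signal.
- **Annotators** (default 29): P(correct) = σ(3.1 − 4.0·u) where u is the
  machine annotator's uncertainty for the triplet — the difficulty proxy
  is deliberately the same construct the analysis studies.  The intercept
  is calibrated so pooled correctness sits near 0.5 at the default
  cohort's difficulty distribution, as observed in the lab study.  Stated
  uncertainty is round(−1 + 3u + propensity + noise) clipped to 0–3, with
  a N(0, 0.5²) per-annotator propensity.  Duration is
  45 + speed_offset − 0.7·ordinal + 7.0·stated_u + N(0, 8²) seconds,
  floored at 1 s; the per-ordinal decay and per-level increment match the
  magnitudes reported for the real experiment, and the N(0, 8²)
  per-annotator speed offset realises the individual-trait argument that
  motivates the random intercept.
- **EDA**: one continuous series per annotator at 4 Hz spanning the summed
  durations — tonic level ~ N(2.0, 0.5²) μS, within-series noise sd
  0.15 μS, and *no* ordinal trend by default, so the triplet-ID→EDA
  association is null by construction and serves as a type-I-error probe.

What the simulation does **not** emulate: the shared per-task biases that
made real annotators agree unanimously on wrong labels (errors here are
independent given difficulty), expert annotators, real marginal
distributions, and sensor artifacts.  Consequently the simulated
inter-rater α is much lower than the published 0.593 even at matched
correctness, and passing simulation tests demonstrates the machinery's
statistical correctness (parameter recovery, error calibration), not
behavioural realism of crowd dynamics.

## Problem sizes used in the checks

Parameter recovery runs 100 seeded replicates at the study's dimensions
(29 annotators × 27 tasks after the acclimatization skip) and requires the
mean recovered stated-U→duration effect within 15 % of the planted 7.0 s;
the null EDA association is checked over 200 replicates against a ~4-sd
binomial band around the nominal 5 % rejection rate.  The fixture-based
statistics are exact desk-scale computations.

## Known limitations

- α is implemented for complete binary (two-category) rating grids — the
  sufficient-statistics path does not cover missing ratings or more
  categories.
- The logistic mixed model's variational posterior can understate
  uncertainty relative to a likelihood-based GLMM; treat its CIs as
  approximate.
- The two-decimal agreement-flag rule is tied to ratios printed at two
  decimals; applying it to raw counts is exact only because n = 29 keeps
  rounding unambiguous.
- The EDA segmentation assumes durations tile the recording exactly from
  the start marker; gaps between tasks are not modelled.
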