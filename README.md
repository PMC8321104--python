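# tripletlab

Tools for analysing how difficult **similarity-based (triplet) annotation**
of medical records is, for researchers who study crowdsourced labelling of
clinical data.

A triplet task shows an annotator three records described by ten risk-factor
variables: a left anchor **A** from an individual with hepatic steatosis
(MRI liver-fat fraction ≥ 14 %), a right anchor **C** from a healthy
individual (≤ 5 %), and a middle record **B** whose class is hidden.  The
annotator assigns B to the more similar anchor and states an ordinal
uncertainty (0 = very certain … 3 = very uncertain); task duration and
electrodermal activity (EDA, μS) are recorded alongside.  The package
implements the full analysis stack for such experiments:

- **ASBA**, a deterministic similarity-based machine annotator: 1-nearest
  neighbour under the Heterogeneous Euclidean-Overlap Metric
  (HEOM(a, b) = √Σ_v d_v², with d_v the 0/1 overlap for nominal variables
  and the range-normalised absolute difference for continuous ones), with
  intrinsic uncertainty ASBA_U(t) = smallest_distance(t) / largest_distance(t)
  and its 4-level (round(3·ASBA_U)) and binary (ASBA_U ≥ τ_ASBA, τ_ASBA = 0.5)
  discretisations.
- **Agreement and correctness metrics**: per-annotator and per-triplet
  correctness, stated-uncertainty summaries, vote tallies with the
  normalised majority agrm(t) = max{voteFor(t,A), voteFor(t,C)}/n and its
  thresholded flags (τ ∈ {2/3, 3/4}), nominal **Krippendorff's α**, the
  binary-uncertainty × correctness contingency table with Pearson χ², and
  count reconstruction from printed 2-decimal vote ratios.
- **EDA processing**: segmentation of per-annotator recordings by recorded
  task durations and 10-second-sampled segment means.
- **Mixed-effects association suite**: random-intercept models (linear for
  duration/EDA outcomes, logistic with odds-ratio reporting for binary
  correctness) over the exposure→outcome grid used in this experimental
  design, plus acclimatization summaries.
- **Synthetic data generators** for the cohort, annotator behaviour and
  EDA recordings, so the entire pipeline is testable end to end without
  access-restricted cohort data.

## Worked example

```python
import tripletlab as tl

# reference tables transcribed from the published experiment
table7 = tl.load_fixture("table7")
counts = tl.vote_counts_from_ratios(table7, n=29)   # reconstruct integer votes
truth = dict(zip(table7["triplet_id"], table7["correct_label"]))

alpha = tl.krippendorff_alpha(counts)
print(f"alpha = {alpha:.3f} ({tl.metrics.alpha_reliability_label(alpha)})")
# alpha = 0.593 (unreliable)

stat, p = tl.chi_square_2x2(tl.load_table4_counts())
print(f"chi2 = {stat:.3f}, p = {p:.3f}")
# chi2 = 2.692, p = 0.101

from tripletlab.metrics import erroneous_agreement_count
print(erroneous_agreement_count(counts, truth, 2 / 3))
# 14
```

The α of 0.593 sits below the conventional 0.667 "lowest conceivable"
reliability bound: the annotator group as a whole was unreliable on this
task.  The χ² p-value of 0.101 means stated certainty was *not*
significantly associated with correctness, and 14 of the 30 triplets show
the group agreeing (two-thirds majority) on the *wrong* label — high
agreement does not imply a correct annotation.

A fully simulated study runs from one seed:

```python
report = tl.run_pipeline(seed=1)
report.write("out/")          # CSV reports + summary.json
```

or from the shell:

```
tripletlab run-all --seed 1 --out-dir out/
tripletlab report --out-dir out/   # fixture-based reference statistics
```

## Layout

| module | contents |
| --- | --- |
| `tripletlab.datatypes` | `CohortRecord`, `Triplet`, `AnnotationMatrix`, `EDATimeSeries` |
| `tripletlab.io` | CSV readers/writers, packaged reference tables |
| `tripletlab.triplets` | steatosis classes, 45+45 sampling, six-group triplet construction |
| `tripletlab.asba` | HEOM, machine annotator, uncertainty discretisation |
| `tripletlab.metrics` | correctness, agreement, α, contingency, χ² |
| `tripletlab.eda` | duration-based segmentation, 10-s-sampled means |
| `tripletlab.models` | random-intercept association suite, acclimatization |
| `tripletlab.simulate` | cohort/annotator/EDA generators |
| `tripletlab.pipeline`, `tripletlab.cli` | orchestration and `tripletlab` CLI |

See `docs/methods.md` for the modelling details and design choices.
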