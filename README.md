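# imagcond

**Differential fear conditioning with imagined conditioned stimuli: a tested,
reusable analysis pipeline on synthetic cohorts.**

Humans can acquire fear of a stimulus they have only *imagined* being paired
with a shock, and that fear generalizes between imagined and viewed percepts.
The experimental paradigm behind this package conditions participants in two
phases — an *imagery acquisition* phase (imagined CS+ reinforced at 50%) and a
*visual acquisition* phase (viewed CS+ reinforced at 50%) — and measures
conditioned responding with self-reported fear, skin conductance (SCR), and
fMRI multivoxel pattern analysis (MVPA). This package re-implements the
computational core of that study as a library:

- **`imagcond.design`** — constrained trial-schedule generation: per phase,
  6 habituation runs × 8 trials and 6 acquisition runs × 12 trials, with fixed
  CS− run endpoints, an early first reinforcement in run 1, one reinforced
  CS+ per run half thereafter, a full invariant validator, the analysis-trial
  exclusion rules (no shock trials, no boundary CS−), and BIDS-style events
  TSV I/O.
- **`imagcond.scr`** — trough-to-peak SCR scoring: amplitude = max over
  1–6 s post-onset minus the mean over 0–1 s, floored at 0.02 µS,
  square-root transformed, aggregated to condition means.
- **`imagcond.glm`** — trial-wise ("least squares all") beta-series GLM with
  a unit-peak double-gamma HRF (peaks 6 s / 16 s, undershoot ratio 1/6),
  nuisance columns for shock and boundary trials, OLS estimation, and
  per-voxel z-scored trial patterns.
- **`imagcond.mvpa`** — CS+ vs CS− cross-classification with a linear SVM
  (C = 1), optional top-*k* univariate feature selection (training data
  only), and two-level inference: per-participant label-permutation nulls
  and a group bootstrap that draws one permuted accuracy per participant per
  iteration; one-sided add-one empirical p.
- **`imagcond.stats`** — paired *t* with Cohen's *d = t/√n*, the two-sided
  JZS Bayes factor BF₁₀(r) with a Cauchy(0, r) effect-size prior
  (default r = 0.707, adaptive quadrature), and a classical within-subject
  2×2×2 RM-ANOVA (CS type × modality × phase) reporting
  η² = SS_effect / SS_total.
- **`imagcond.synth`** — the synthetic cohort generator: seeded,
  deterministic SCR traces, ROI trial patterns whose view/imagine
  discriminative directions share a controllable fraction of their energy,
  BOLD runs with known betas and AR(1) noise, and 7-point Likert ratings.
- **`imagcond.pipeline` / `imagcond` CLI** — end-to-end orchestration with a
  single global seed, config hashing, and a reproducibility report.

## The model in brief

For participant *s*, an analysis trial of modality *m* ∈ {view, imagine} and
class *c* ∈ {CS+, CS−} yields a voxel pattern

x = ±(δₛ/2)·u⁽ᵐ⁾ + ε,  ε ~ N(0, σ²I),  u⁽ᵛⁱᵉʷ⁾·u⁽ⁱᵐᵃᵍⁱⁿᵉ⁾ = ρ,

where δₛ is the participant's pattern separation (normal hyperprior around
the cohort effect) and ρ (`shared_fraction`) sets how much of the
discriminative direction is shared between modalities. The optimal
within-modality accuracy is Φ(δ/2σ); cross-modality transfer rises from
chance (ρ = 0) to the within-modality level (ρ = 1). Group inference follows
the two-level scheme: per participant, accuracies from classifiers retrained
on permuted training labels; at the group level, bootstrap means of one
permuted accuracy per participant, against which the observed group-mean
accuracy is compared one-sided.

## Worked example

```python
from imagcond import stats

# Bayes factor for a paired design from a printed t statistic (n = 27)
print(stats.jzs_bf10(1.17, 27).bf01)   # 2.651  -> anecdotal support for H0
print(stats.jzs_bf10(6.11, 27).bf10)   # 10058  -> decisive support for H1
print(round(6.11 / 27**0.5, 2))        # 1.18   -> Cohen's d for t(26)=6.11
```

Full pipeline on a small demo cohort (8 participants, 60-voxel ROI):

```bash
imagcond run --out demo_out
```

This writes events TSVs, SCR scores and condition means, pattern matrices,
decoding results, and statistics tables. Typical `mvpa_summary.json` entries
under the demo's default effect sizes look like

```
imagery_acquisition:imagine->visual_acquisition:view  acc 0.495  p 0.647  null 0.501
visual_acquisition:view->imagery_acquisition:imagine  acc 0.562  p 0.119  null 0.512
```

— group-mean decoding accuracy, its empirical p against the bootstrap null,
and the null's mean (≈0.50, the chance anchor for a balanced design). The
accompanying `ttests.tsv` shows the SCR differential (CS+ > CS−) with large
*t* and BF₁₀ in the conditioned modality, and `anova.tsv` the 2×2×2
RM-ANOVA per measure.

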