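# muerd

Single-subject EEG mu-rhythm ERD/ERS analysis comparing two baseline
conditions, with a synthetic-EEG generator for end-to-end validation.

## The problem

In pediatric action-observation / action-execution (AO/AE) experiments,
mu-rhythm desynchronization is quantified as the percentage change of
mu-band power relative to a baseline:

    ERD/ERS = (A − R) / R × 100

where `A` is the band power of an event epoch and `R` the mean band power
of the baseline; negative values indicate desynchronization.  Because the
measure is a ratio in `R`, the choice of baseline can decide whether a
desynchronization is found at all.  `muerd` implements a complete
single-subject pipeline for a toddler button-press paradigm with two
baselines — a 30 s static-image presentation (**BL1**) and 2 s stillness
periods at the start of each trial (**BL2**) — and answers, per subject:

1. does the subject significantly suppress the mu rhythm during action
   execution (*suppressive* vs *non-suppressive*), and
2. which baseline yields the deeper ERD (the *preferred* baseline)?

The pipeline covers preprocessing (1–45 Hz FIR filtering, flat-line and
correlation-based bad-channel detection with spherical-spline
interpolation, artifact-window and 200 µV epoch rejection, average
reference), Welch log-spectra (250-sample Hamming windows, 125-sample
overlap, log10(1 + PSD)), personalized 3 Hz mu-band selection (the most
AE-attenuated frequency in 4–13 Hz, averaged over channels), per-epoch
cluster-level ERD over seven scalp clusters, one-sample and paired
Wilcoxon signed-rank statistics with a step-up false-coverage-rate
adjustment across the 7-cluster family (α = 0.050), and the cohort-level
classification and baseline-preference rules.  A synthetic-data module
generates 250 Hz, 60-channel recordings with a controllable mu rhythm over
a 1/f background so every stage can be tested against ground truth.
See `docs/methods.md` for the full model description.

## Worked example

Generate a synthetic subject with a 7 Hz mu rhythm, stronger mu during the
static-image baseline (6 µV vs 4 µV), and 50 % amplitude suppression
during execution, then run the full analysis:

```python
from muerd import SubjectScenario, generate_subject, make_default_layout, run_subject

layout = make_default_layout()            # 60 channels, 7 scalp clusters
scenario = SubjectScenario(subject_id="S1", mu_center_freq=7,
                           mu_amp_bl1=6.0, mu_amp_bl2=4.0,
                           suppression_ae=0.5, suppression_ao=0.6,
                           n_trials=15, seed=42)
rec, ann = generate_subject(scenario, layout)
analysis = run_subject(rec, ann, layout, subject_id="S1")
r = analysis.result
print(r.group, r.preference, r.mu_band_center, round(r.lateralized_score, 2))
```

Output:

```
suppressive BL1 {'BL1': 7, 'BL2': 7} 0.57
```

The subject is classified *suppressive* (significant mu desynchronization
during AE), prefers **BL1** — as encoded by the larger BL1 mu amplitude —
the personalized band is centred at the true 7 Hz for both baselines, and
the hand-use lateralization score of 0.57 reflects the right-hand-majority
trial labels.  Cluster-level detail is in `analysis.onesample`; e.g. the
left-central cluster scored against BL2 has a median AE ERD of −56 %
(adjusted p < 0.05):

```python
ae_bl2 = {t.cluster: t for t in analysis.onesample[("AE", "BL2")]}
print(round(ae_bl2["C_left"].median), ae_bl2["C_left"].significant)
# -56 True
```

A thin CLI wraps the same functions:

```bash
mu-pipeline simulate --subjects 12 --seed 1 --out-dir data/
mu-pipeline run --data-dir data/ --out results/
mu-pipeline summarize --table-ae src/muerd/data/table2.csv \
                      --table-ao src/muerd/data/table3.csv
```

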