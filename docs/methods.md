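# Methods

## Scientific setting

`muerd` implements a single-subject analysis of EEG mu-rhythm
event-related desynchronization/synchronization (ERD/ERS) in a toddler
action-observation / action-execution (AO/AE) paradigm that compares two
baseline conditions: a 30 s static-image presentation at the start of the
session (BL1) and 2 s stillness periods at the start of every trial (BL2).
ERD/ERS is the percentage change of mu-band power in an event epoch
relative to a baseline,

    ERD/ERS = (A - R) / R x 100,

with A the event-epoch band power and R the mean baseline band power;
negative values are desynchronization.  Because ERD is a ratio in R, the
choice of baseline directly shapes the outcome: a subject whose mu power is
higher during one baseline will show deeper ERD against that baseline.
The pipeline quantifies exactly this effect per subject, classifies
subjects as suppressive or non-suppressive, and determines each
suppressive subject's preferred baseline.

## Pipeline

Stages run in a fixed order per subject; channel count and order are
preserved end-to-end, only time/epochs are removed.

1. **Band-pass filter** — zero-phase windowed-sinc FIR (Hamming), 1-45 Hz
   corners, transition bandwidths 1 Hz (high-pass) and 5 Hz (low-pass),
   applied via `mne.filter.filter_data`.  Only the corner frequencies are
   scientific commitments; the transition widths are design choices that
   keep passband ripple below 1 dB while attenuating 60 Hz by over 20 dB.
2. **Bad channels** — flat-line longer than 5 s, or correlation with the
   channel's spherical-spline reconstruction below 0.85 in more than 40 %
   of 5 s windows.  Detection is iterated to a fixed point with flagged
   channels excluded from the reconstructions, so one noisy electrode does
   not drag its neighbours below threshold.  More than 15 % flagged
   channels invalidates the subject.  Flagged channels are replaced by
   spherical-spline estimates (Perrin-style, order m = 4, 7 Legendre
   terms, 1e-5 stiffness regularization, with an intercept term so
   constant fields are reproduced exactly).
3. **Continuous-window rejection** — 1 s windows in which more than 50 %
   of channels exceed 200 uV peak-to-peak are marked rejected; the
   kept-time mask propagates to segmentation.  200 uV is the single
   amplitude threshold used throughout, so "contaminated" has one coherent
   definition.
4. **Average reference**, then **segmentation**: BL2 epochs are
   [onset, onset + 2 s); AO/AE epochs are the 1500 ms before the annotated
   button press, which approximates the arm-movement-to-culmination span;
   BL1 is kept as contiguous valid segments totalling at most 30 s.
   Epochs are half-open sample intervals with 0-based indexing.  Epochs
   marked invalid in the annotation file (standing in for video-based
   behavioural coding) or touching rejected time are dropped with a logged
   reason.
5. **Epoch rejection** — any |sample| > 200 uV removes the epoch.  Fewer
   than 5 surviving epochs in any condition flags the subject
   insufficient-data; flagged subjects are excluded from all cohort
   denominators.

## Spectra and the personalized mu band

PSD is estimated per epoch and channel by Welch's method: 250-sample
Hamming windows with 125-sample overlap (at 250 Hz this yields a 1 Hz
grid; 3 windows per BL2 epoch, 2 per AO/AE epoch), then log-transformed as
log10(1 + PSD).  BL1 is pooled into a single Welch estimate across all its
segments, weighted by window count; windows never straddle segment
boundaries.  A MAD-based outlier screen (per condition, broadband 4-13 Hz
log power, strict 3 scaled-MAD cut) removes unstable epochs before any
band selection.

Because the toddler mu peak shifts with age, the analysis band is
personalized: per channel, the frequency in 4-13 Hz with the largest
baseline-minus-AE difference of mean log-PSD is found (ties break toward
the lower frequency); the per-channel frequencies are averaged over all
scalp channels, rounded half-up to an integer, clamped so the +/-1 Hz band
stays within 4-13 Hz, and the 3 Hz band centred there is used.  The band
is selected separately for each baseline.  Attenuation is computed on the
log-transformed PSD by default — the stated processing order applies the
log before all later analysis — with `power_scale="raw"` available as a
sensitivity switch; the same switch governs the ERD power scale.

## ERD table and statistics

Band power is the mean log-PSD over the band's 3 bins.  R for BL2 is the
mean over all valid BL2 epochs of the session (not trial-matched; with 2 s
epochs this maximizes the stability of the reference), and for BL1 the
pooled Welch estimate.  Per-channel ERD values are averaged, unweighted,
within seven scalp clusters (frontal, central, parietal x left/right, plus
occipital); channels outside the partition are excluded.  Interpolated
channels do enter cluster means and are listed in the QC report.

Per subject, condition and baseline, the 7 cluster ERD samples (one value
per epoch) are tested against a zero median with two-sided one-sample
Wilcoxon signed-rank tests; BL1-based and BL2-based ERD of the same event
epochs are compared with paired Wilcoxon tests.  Zeros are dropped before
ranking; the exact null distribution (equivalent to enumerating the 2^n
sign assignments) is used for n <= 25 without ties, otherwise the normal
approximation with tie and continuity corrections.  Each 7-cluster family
is corrected with a step-up false-coverage-rate adjustment
(Benjamini-Hochberg type step-up over the family; the selection at
adjusted p < alpha controls the stated rate), at alpha = 0.050.  A cluster
counts as significant desynchronization only when the adjusted p is below
alpha *and* the cluster median is negative, so strong synchronization is
never starred.  Group contrasts (e.g. epoch counts between groups) use
two-sided Wilcoxon rank-sum tests, exact for min(n) <= 10 without ties.

## Classification and baseline preference

* **Suppressive**: at least one cluster significant during AE for at least
  one baseline; otherwise non-suppressive.  The rule also reports whether
  both baselines individually yield a significant cluster.
* **Preference**: among clusters with a significant adjusted paired p,
  count those whose BL1-referenced median ERD is more negative than the
  BL2-referenced one, and vice versa; a strict majority wins, a tie or an
  empty set means no preference.  The majority rule is induced from the
  published per-subject tables, where subjects with mixed cluster
  directions resolve to the majority side.
* **AO confirmation**: the same preference rule applied to AO; paired
  tests are only consulted for conditions with at least one significant
  one-sample cluster (matching the published analysis, which ran paired
  tests only after a significant desynchronization was found).  AO
  preference equal to the AE preference is "confirmed", an AO preference
  of none is "undetermined", anything else "switched".

Cohort percentages are reported to one decimal, rounded half-up: group
rates over all included subjects, preference and AO-confirmation rates
over the suppressive group.

The two packaged summary tables (`data/table2.csv` for AE,
`data/table3.csv` for AO; long format, one row per subject x cluster x
baseline) feed the same rule code through `ingest_summary_table`, so the
headline rates can be re-derived from printed per-subject summaries
without raw EEG.  Printed inequality p-values are kept as strings
("<0.001", ">0.999") and parsed to a value on the certain side of the cut;
only their position relative to alpha matters to the rules.

## Synthetic data generator

The generator emulates the study's recording conditions: 250 Hz, 60
channels on the upper unit sphere, a 30 s BL1 block, then trials of
2 s BL2 + 1.5 s AO + 1.5 s AE separated by 0.5 s unlabelled
"experimenter-handling" gaps of baseline-like signal (inter-span timing is
a convention, not a reported fact).

* **Mu source**: a sinusoid at an integer centre frequency (5-8 Hz) with
  per-span random phase and N(0, 0.1 Hz) frequency jitter, projected with
  a Gaussian spatial profile (sigma = 1 rad of great-circle distance,
  floor weight 0.15) centred on the left/right central clusters.  The
  oscillation amplitude in each span is the governing baseline amplitude
  times the span's suppression factor (AO/AE amplitudes are tied to the
  within-trial baseline BL2), so expected band power — and hence ERD — is
  analytically predictable: power scales with amplitude squared, e.g.
  suppression 0.5 gives a raw-power ERD of about -75 %.
* **Baseline preference** is encoded by unequal BL1/BL2 mu amplitudes
  (defaults 6 vs 4 uV for a preferring subject); the larger-amplitude
  baseline yields the deeper ERD, which is the mechanism the analysis is
  meant to detect.
* **Background**: Gaussian 1/f^beta noise (beta = 1, scale 1 uV per
  channel), built as a mixture of a spatially smooth shared field (8
  smeared pink-noise sources, 75 % of variance) and a channel-independent
  component (25 %).  The shared field emulates volume conduction; without
  it every channel decorrelates from its spline reconstruction and the
  0.85-correlation rule would flag a clean cap wholesale.
* **Artifacts** on request: flat channels and high-amplitude broadband
  bursts.  Hand-use labels are i.i.d. Bernoulli (default P(right) = 0.75,
  echoing the right-preferring majority of the study sample).
* **Seeding**: one `numpy` Generator per subject, seeded from the
  scenario; cohort subject seeds derive deterministically from a master
  seed via `SeedSequence`.  Identical scenarios produce bit-identical
  recordings.

What the generator does *not* model: ocular/EMG artifact morphology,
realistic head-model forward projection, non-stationary background state
changes, or attention-driven baseline contamination.  Passing recovery
tests therefore show that the pipeline's logic is correct under its own
assumptions, not that those assumptions hold for real toddler EEG.

## Validation problem sizes

Recovery and calibration checks use sizes chosen to keep the suite quick
while leaving the statistics well away from their decision boundaries: a
12-subject cohort with strong effects (suppression 0.5, 15 trials,
amplitudes 6/4 uV over 1 uV noise) for ground-truth recovery of group
labels and preferences; 500 simulated zero-median 7-cluster families
(15 epochs, inter-cluster correlation 0.5) for the family-wise
false-positive rate; 20 subjects for mu-band centre recovery; enumeration
oracles at n <= 10 for exact p-values and 1000 random families for the
step-up adjustment.  The null calibration runs at the ERD-sample level
rather than through 500 full EEG simulations; the statistical family it
exercises is identical to the one the pipeline produces.

## Numerical conventions and edge cases

* Argmax ties in band selection break toward the lowest frequency; with no
  attenuation anywhere the band is still returned with a warning flag.
* The outlier screen uses a strict inequality: an epoch exactly at the
  3-MAD boundary is kept; a zero MAD flags nothing.
* Degenerate signed-rank inputs (all zeros, or identical paired samples)
  return p = 1 rather than raising.
* IQRs use linear quantile interpolation by default (`iqr_method`
  exposes the convention, since the printed tables do not state theirs).
* EDF output is plain 16-bit EDF with per-channel physical scaling; the
  quantization step is (channel range)/65535.  Reading goes through MNE's
  EDF reader.
* Percentages are rounded half-up to one decimal to match printed-table
  conventions.

## Known limitations

* One-sample tests are two-sided with a negative-median side condition;
  whether the original analysis was one- or two-sided is not stated.
* The >50 %-of-channels window-rejection rule operationalizes
  "contaminated" as peak-to-peak > 200 uV; other artifact definitions
  would change which seconds are dropped.
* Visual-inspection steps of the original workflow are replaced by the
  automatic criteria plus annotation validity flags; the pipeline is fully
  deterministic but cannot reproduce judgement calls.
* The preference rule needs at least one significant paired cluster;
  subjects with genuine but sub-threshold preferences are reported as
  having none.
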