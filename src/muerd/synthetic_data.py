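"""Synthetic toddler EEG with a controllable mu rhythm.

Generates 250 Hz multichannel recordings with the session structure the
analysis expects -- a 30 s static-image baseline (BL1) followed by trials of
2 s stillness (BL2), 1.5 s action observation (AO) and 1.5 s action
execution (AE) -- so that every downstream stage can be exercised against a
known ground truth.

Signal model, per subject:

* a mu oscillation: an amplitude-modulated sinusoid at an integer centre
  frequency (5-8 Hz) with small per-span phase/frequency jitter, projected
  onto the cap with a Gaussian spatial profile centred on the left and right
  central clusters (plus a small floor, since the toddler mu field is
  broad).  The oscillation amplitude in each span is the relevant baseline
  amplitude times the span's suppression factor, so band power - and hence
  the expected ERD - is analytically predictable (power scales with
  amplitude squared).
* a 1/f^beta background: a spatially smooth shared pink-noise field (a few
  smeared sources, emulating volume conduction) mixed with a
  channel-independent pink component.  Without the shared field every
  channel would decorrelate from its spherical-spline reconstruction and the
  0.85-correlation bad-channel rule would reject a clean cap.
* optional injected artifacts: flat channels and high-amplitude bursts.

A baseline preference is encoded by giving the two baselines different mu
amplitudes: the task-span amplitude is tied to the within-trial baseline
(BL2), so the baseline with the larger mu amplitude yields the deeper
(more negative) ERD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotationSet,
    ChannelLayout,
    ConfigurationError,
    Recording,
    write_annotations_csv,
    write_edf,
)

__all__ = [
    "ArtifactSpec",
    "CohortMember",
    "CohortScenario",
    "SubjectScenario",
    "generate_cohort",
    "generate_subject",
    "make_cohort_scenario",
    "mu_channel_weights",
    "scenario_from_yaml",
    "scenario_to_yaml",
    "write_subject_dataset",
]

#: seconds of baseline-like signal between labelled spans (experimenter
#: handling time; not part of any analysis epoch)
GAP_S = 0.5

#: width (radians of great-circle distance) of the Gaussian mu field
MU_SIGMA_RAD = 1.0
#: minimum mu projection weight anywhere on the cap
MU_FLOOR = 0.15

#: fraction of background variance carried by the shared (spatially smooth)
#: pink-noise field; the remainder is channel-independent
SHARED_NOISE_FRACTION = 0.75
N_SHARED_SOURCES = 8
SHARED_SOURCE_SIGMA_RAD = 0.8


@dataclass
class ArtifactSpec:
    """One injected artifact.

    kind: ``"flat_channel"`` (zero the channel over the span) or ``"burst"``
    (add high-amplitude broadband noise).  ``channel`` may be ``None`` for a
    burst hitting every channel.
    """

    kind: str
    channel: int | None
    span_s: tuple[float, float]
    amplitude_uv: float = 500.0

    def __post_init__(self) -> None:
        if self.kind not in ("flat_channel", "burst"):
            raise ConfigurationError(f"unknown artifact kind {self.kind!r}")
        if self.kind == "flat_channel" and self.channel is None:
            raise ConfigurationError("flat_channel artifact needs a channel index")


@dataclass
class SubjectScenario:
    """Ground-truth description of one synthetic subject."""

    subject_id: str
    mu_center_freq: int = 7  # Hz, integer in 5..8
    mu_amp_bl1: float = 6.0  # uV
    mu_amp_bl2: float = 4.0  # uV
    suppression_ao: float = 0.6  # amplitude multiplier during AO
    suppression_ae: float = 0.5  # amplitude multiplier during AE
    noise_exponent: float = 1.0  # 1/f^beta slope
    noise_scale: float = 1.0  # uV (background std per channel)
    n_trials: int = 15
    seed: int = 0
    p_right: float = 0.75  # per-trial probability of right-hand press
    artifact_spec: list[ArtifactSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.suppression_ao <= 1 and 0 <= self.suppression_ae <= 1):
            raise ConfigurationError("suppression factors must be in [0, 1]")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.noise_scale <= 0 or self.mu_amp_bl1 < 0 or self.mu_amp_bl2 < 0:
            raise ConfigurationError("amplitudes/noise scale must be positive")
        if not 5 <= int(self.mu_center_freq) <= 8:
            raise ConfigurationError("mu_center_freq must be an integer in 5..8")

    # ground truth used by recovery tests -------------------------------
    @property
    def truth_suppressive(self) -> bool:
        return self.suppression_ae < 1.0

    @property
    def truth_preference(self) -> str:
        if not self.truth_suppressive:
            return "NA"
        if self.mu_amp_bl1 > self.mu_amp_bl2:
            return "BL1"
        if self.mu_amp_bl2 > self.mu_amp_bl1:
            return "BL2"
        return "none"


@dataclass
class CohortScenario:
    subjects: list[SubjectScenario]
    proportion_suppressive: float = 0.75
    proportion_bl1_preferring: float = 0.75
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.proportion_suppressive <= 1
                and 0 <= self.proportion_bl1_preferring <= 1):
            raise ConfigurationError("proportions must be in [0, 1]")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate subject_id in cohort")


@dataclass
class CohortMember:
    scenario: SubjectScenario
    recording: Recording
    annotations: AnnotationSet


# ---------------------------------------------------------------------------
# spatial helpers
# ---------------------------------------------------------------------------


def _gc_dist(pos: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Great-circle distance (radians) from each row of pos to center."""
    c = np.clip(pos @ center, -1.0, 1.0)
    return np.arccos(c)


def mu_channel_weights(layout: ChannelLayout) -> np.ndarray:
    """Mu projection weight per channel, in (0, 1], max 1 at the central
    cluster centroids."""
    pos = layout.positions
    idx = layout.cluster_indices()
    w = np.zeros(len(pos))
    for cl in ("C_left", "C_right"):
        center = pos[idx[cl]].mean(axis=0)
        center /= np.linalg.norm(center)
        w = np.maximum(w, np.exp(-_gc_dist(pos, center) ** 2 / (2 * MU_SIGMA_RAD ** 2)))
    return MU_FLOOR + (1 - MU_FLOOR) * w


def _pink_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                sfreq: float, beta: float) -> np.ndarray:
    """Unit-variance Gaussian 1/f^beta noise, one row per series."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.ones_like(freqs)
    nz = freqs >= 1.0  # flatten below 1 Hz (high-pass region) to avoid blow-up
    shape[nz] = freqs[nz] ** (-beta / 2.0)
    shape[~nz] = 1.0
    spec *= shape
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------


def _span_plan(scn: SubjectScenario, sfreq: float) -> list[tuple[str, float, float, int]]:
    """(label, duration_s, mu_amplitude_uv, trial_index) in session order.

    Labels: BL1/BL2/AO/AE plus unlabelled "gap" spans of baseline-like
    signal between events.
    """
    plan: list[tuple[str, float, float, int]] = [("BL1", 30.0, scn.mu_amp_bl1, -1)]
    for t in range(scn.n_trials):
        plan.append(("gap", GAP_S, scn.mu_amp_bl2, t))
        plan.append(("BL2", 2.0, scn.mu_amp_bl2, t))
        plan.append(("gap", GAP_S, scn.mu_amp_bl2, t))
        plan.append(("AO", 1.5, scn.suppression_ao * scn.mu_amp_bl2, t))
        plan.append(("gap", GAP_S, scn.mu_amp_bl2, t))
        plan.append(("AE", 1.5, scn.suppression_ae * scn.mu_amp_bl2, t))
    return plan


def generate_subject(scenario: SubjectScenario, layout: ChannelLayout,
                     sfreq: float = 250.0) -> tuple[Recording, AnnotationSet]:
    """Generate one subject's recording and annotation set.

    Deterministic given the scenario (including its seed).
    """
    if sfreq <= 0:
        raise ConfigurationError("sfreq must be positive")
    if len(layout.channel_names) < 2:
        raise ConfigurationError("layout needs at least 2 channels")

    rng = np.random.default_rng(scenario.seed)
    plan = _span_plan(scenario, sfreq)
    n_samples = int(round(sum(d for _, d, _, _ in plan) * sfreq))
    n_ch = len(layout.channel_names)
    pos = layout.positions

    # --- mu oscillation -------------------------------------------------
    weights = mu_channel_weights(layout)
    mu = np.zeros(n_samples)
    cursor = 0
    rows = []
    for label, dur_s, amp, trial in plan:
        n = int(round(dur_s * sfreq))
        t = np.arange(n) / sfreq
        f = scenario.mu_center_freq + rng.normal(0.0, 0.1)
        phase = rng.uniform(0, 2 * np.pi)
        mu[cursor : cursor + n] = amp * np.sin(2 * np.pi * f * t + phase)
        onset_s = cursor / sfreq
        if label != "gap":
            rows.append((onset_s, dur_s, label, trial))
        cursor += n

    # --- background noise ----------------------------------------------
    beta = scenario.noise_exponent
    indep = _pink_noise(rng, n_ch, n_samples, sfreq, beta)
    sources = _pink_noise(rng, N_SHARED_SOURCES, n_samples, sfreq, beta)
    centers = rng.standard_normal((N_SHARED_SOURCES, 3))
    centers[:, 2] = np.abs(centers[:, 2])  # sources under the upper cap
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    gains = np.stack(
        [np.exp(-_gc_dist(pos, c) ** 2 / (2 * SHARED_SOURCE_SIGMA_RAD ** 2)) for c in centers],
        axis=1,
    )  # (n_ch, K)
    shared = gains @ sources
    shared /= shared.std(axis=1, keepdims=True)
    rho = SHARED_NOISE_FRACTION
    noise = scenario.noise_scale * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * indep)

    data = weights[:, None] * mu[None, :] + noise

    # --- artifacts ------------------------------------------------------
    for art in scenario.artifact_spec:
        a = int(round(art.span_s[0] * sfreq))
        b = int(round(art.span_s[1] * sfreq))
        a, b = max(a, 0), min(b, n_samples)
        if b <= a:
            raise ConfigurationError(f"empty artifact span {art.span_s}")
        if art.kind == "flat_channel":
            data[art.channel, a:b] = 0.0
        else:  # burst
            burst = art.amplitude_uv * rng.standard_normal(b - a)
            if art.channel is None:
                data[:, a:b] += burst[None, :]
            else:
                data[art.channel, a:b] += burst

    # --- annotations ----------------------------------------------------
    hands = []
    for onset, dur, label, trial in rows:
        if label == "AE":
            hands.append("R" if rng.random() < scenario.p_right else "L")
        else:
            hands.append("NA")
    ann = AnnotationSet(
        pd.DataFrame(
            {
                "onset_s": [r[0] for r in rows],
                "duration_s": [r[1] for r in rows],
                "condition": [r[2] for r in rows],
                "trial_index": [r[3] for r in rows],
                "valid": 1,
                "hand": hands,
            }
        )
    )
    rec = Recording(data=data, sfreq=sfreq,
                    channel_names=list(layout.channel_names), positions=pos.copy())
    return rec, ann


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _subject_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def make_cohort_scenario(
    n_subjects: int,
    proportion_suppressive: float = 0.75,
    proportion_bl1_preferring: float = 0.75,
    master_seed: int = 0,
    n_trials: int = 15,
    suppression_ae: float = 0.5,
    suppression_ao: float = 0.6,
    amp_strong: float = 6.0,
    amp_weak: float = 4.0,
    noise_scale: float = 1.0,
) -> CohortScenario:
    """Build a deterministic cohort scenario.

    The first ``round(n * proportion_suppressive)`` subjects are suppressive;
    among those, the first ``round(n_supp * proportion_bl1_preferring)``
    prefer BL1 (larger BL1 mu amplitude), the rest prefer BL2.
    Non-suppressive subjects have suppression 1 and equal baseline
    amplitudes.  Mu centre frequencies cycle through 5-8 Hz.
    """
    if n_subjects < 1:
        raise ConfigurationError("cohort must be non-empty")
    n_supp = int(round(n_subjects * proportion_suppressive))
    n_bl1 = int(round(n_supp * proportion_bl1_preferring))
    seeds = _subject_seeds(master_seed, n_subjects)
    subjects = []
    for i in range(n_subjects):
        center = 5 + (i % 4)
        if i < n_supp:
            bl1_pref = i < n_bl1
            scn = SubjectScenario(
                subject_id=f"SYN{i + 1:02d}",
                mu_center_freq=center,
                mu_amp_bl1=amp_strong if bl1_pref else amp_weak,
                mu_amp_bl2=amp_weak if bl1_pref else amp_strong,
                suppression_ao=suppression_ao,
                suppression_ae=suppression_ae,
                noise_scale=noise_scale,
                n_trials=n_trials,
                seed=seeds[i],
            )
        else:
            scn = SubjectScenario(
                subject_id=f"SYN{i + 1:02d}",
                mu_center_freq=center,
                mu_amp_bl1=(amp_strong + amp_weak) / 2,
                mu_amp_bl2=(amp_strong + amp_weak) / 2,
                suppression_ao=1.0,
                suppression_ae=1.0,
                noise_scale=noise_scale,
                n_trials=n_trials,
                seed=seeds[i],
            )
        subjects.append(scn)
    return CohortScenario(
        subjects=subjects,
        proportion_suppressive=proportion_suppressive,
        proportion_bl1_preferring=proportion_bl1_preferring,
        master_seed=master_seed,
    )


def generate_cohort(cohort: CohortScenario, layout: ChannelLayout,
                    sfreq: float = 250.0) -> list[CohortMember]:
    """Generate one dataset per scenario; ground truth travels with each
    member via its scenario (`truth_suppressive`, `truth_preference`)."""
    if not cohort.subjects:
        raise ConfigurationError("cohort must be non-empty")
    members = []
    for scn in cohort.subjects:
        rec, ann = generate_subject(scn, layout, sfreq=sfreq)
        members.append(CohortMember(scenario=scn, recording=rec, annotations=ann))
    return members


def scenario_to_yaml(cohort: CohortScenario, path: str | Path) -> None:
    """Persist a cohort scenario as plain YAML (one mapping per subject;
    artifact entries as [kind, channel, t0_s, t1_s, amplitude_uv] lists)."""
    import yaml

    doc = {
        "proportion_suppressive": cohort.proportion_suppressive,
        "proportion_bl1_preferring": cohort.proportion_bl1_preferring,
        "master_seed": cohort.master_seed,
        "subjects": [
            {
                "subject_id": s.subject_id,
                "mu_center_freq": s.mu_center_freq,
                "mu_amp_bl1": s.mu_amp_bl1,
                "mu_amp_bl2": s.mu_amp_bl2,
                "suppression_ao": s.suppression_ao,
                "suppression_ae": s.suppression_ae,
                "noise_exponent": s.noise_exponent,
                "noise_scale": s.noise_scale,
                "n_trials": s.n_trials,
                "seed": s.seed,
                "p_right": s.p_right,
                "artifact_spec": [
                    [a.kind, a.channel, a.span_s[0], a.span_s[1], a.amplitude_uv]
                    for a in s.artifact_spec
                ],
            }
            for s in cohort.subjects
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path: str | Path) -> CohortScenario:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    subjects = []
    for s in doc["subjects"]:
        arts = [
            ArtifactSpec(kind=a[0], channel=a[1], span_s=(a[2], a[3]), amplitude_uv=a[4])
            for a in s.pop("artifact_spec", [])
        ]
        subjects.append(SubjectScenario(artifact_spec=arts, **s))
    return CohortScenario(
        subjects=subjects,
        proportion_suppressive=doc.get("proportion_suppressive", 0.75),
        proportion_bl1_preferring=doc.get("proportion_bl1_preferring", 0.75),
        master_seed=doc.get("master_seed", 0),
    )


def write_subject_dataset(member: CohortMember, out_dir: str | Path) -> dict[str, Path]:
    """Write one subject as EDF + annotation CSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = member.scenario.subject_id
    edf = out / f"{sid}.edf"
    csv = out / f"{sid}_annotations.csv"
    write_edf(member.recording, edf)
    write_annotations_csv(member.annotations, csv)
    return {"edf": edf, "annotations": csv}
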