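"""Shared domain types, configuration and file I/O for the mu-ERD pipeline.

The pipeline analyses event-related desynchronization/synchronization
(ERD/ERS) of the EEG mu rhythm in an action-observation / action-execution
(AO/AE) task recorded from toddlers, comparing two baseline conditions:

* ``BL1`` -- a 30 s presentation of a static black-and-white image at the
  start of the session;
* ``BL2`` -- a 2 s period of stillness at the start of every trial.

Recordings are multichannel scalp EEG sampled at 250 Hz with unit-sphere
electrode coordinates.  Channels are grouped into seven scalp clusters
(frontal, central and parietal, each left/right, plus occipital); all
cluster-level quantities in the package refer to this partition.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLUSTERS",
    "CONDITIONS",
    "AnnotationSet",
    "ChannelLayout",
    "ConfigurationError",
    "EpochSet",
    "InsufficientDataError",
    "PipelineConfig",
    "QualityError",
    "Recording",
    "make_default_layout",
    "read_annotations_csv",
    "read_edf",
    "read_layout_csv",
    "round_pct",
    "write_annotations_csv",
    "write_edf",
    "write_layout_csv",
]

#: The seven scalp clusters used for all cluster-level statistics.
CLUSTERS = ("F_left", "F_right", "C_left", "C_right", "P_left", "P_right", "O")

#: Condition labels carried by annotations and epochs.
CONDITIONS = ("BL1", "BL2", "AO", "AE")


class ConfigurationError(ValueError):
    """Invalid scenario, layout or pipeline configuration."""


class QualityError(RuntimeError):
    """Data quality failure that invalidates a subject (too many bad
    channels, all data rejected, ...)."""


class InsufficientDataError(RuntimeError):
    """Too little surviving data to run an analysis step."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunable analysis parameters with their defaults.

    Defaults mirror the published analysis: 1-45 Hz FIR band-pass, flat-line
    and correlation-based bad-channel detection (5 s / 0.85), spherical-spline
    interpolation, >50 %-of-channels window rejection, 200 uV epoch
    rejection, Welch PSD with 250-sample Hamming windows and 125-sample
    overlap, log10(1 + PSD) transform, a personalized 3 Hz mu band searched
    in 4-13 Hz, and Wilcoxon statistics at alpha = 0.050 with a step-up
    false-coverage-rate adjustment over the 7-cluster family.
    """

    # filtering
    hp_hz: float = 1.0
    lp_hz: float = 45.0
    # bad channels
    flat_s: float = 5.0
    corr_thresh: float = 0.85
    corr_window_s: float = 5.0
    corr_bad_fraction: float = 0.4
    max_bad_fraction: float = 0.15
    # continuous window rejection
    reject_window_s: float = 1.0
    reject_chan_fraction: float = 0.5
    amp_thresh_uv: float = 200.0
    # epoching
    bl2_len_s: float = 2.0
    event_len_s: float = 1.5
    bl1_len_s: float = 30.0
    min_epochs_per_condition: int = 5
    # spectra
    welch_nperseg: int = 250
    welch_noverlap: int = 125
    mu_search_lo_hz: float = 4.0
    mu_search_hi_hz: float = 13.0
    outlier_mads: float = 3.0
    # ERD
    power_scale: str = "log1p"  # or "raw"
    # statistics
    alpha: float = 0.050
    exact_max_n: int = 25
    zero_policy: str = "wilcox"
    iqr_method: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.power_scale not in ("log1p", "raw"):
            raise ConfigurationError(f"unknown power_scale {self.power_scale!r}")
        if not 0 < self.hp_hz < self.lp_hz:
            raise ConfigurationError("need 0 < hp_hz < lp_hz")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel EEG in physical units (uV)."""

    data: np.ndarray  # (n_channels, n_samples), uV
    sfreq: float
    channel_names: list[str]
    positions: np.ndarray  # (n_channels, 3) unit-sphere coordinates

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sfreq <= 0:
            raise ConfigurationError(f"sfreq must be positive, got {self.sfreq}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ConfigurationError("data must be (n_channels, n_samples)")
        if self.positions.shape != (len(self.channel_names), 3):
            raise ConfigurationError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ConfigurationError("electrode positions must lie on the unit sphere")
        if np.isnan(self.data).any():
            raise ConfigurationError("recording contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.sfreq, list(self.channel_names),
                         self.positions.copy())


@dataclass
class ChannelLayout:
    """Channel-to-cluster assignment plus electrode geometry.

    ``clusters`` maps every channel name to one of the seven scalp clusters
    or ``"none"`` for channels excluded from cluster averaging (e.g. midline
    leftovers).
    """

    channel_names: list[str]
    positions: np.ndarray  # (n_channels, 3), unit sphere
    clusters: dict[str, str]  # channel name -> cluster or "none"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        missing = [c for c in self.channel_names if c not in self.clusters]
        if missing:
            raise ConfigurationError(f"channels without cluster assignment: {missing}")
        bad = sorted({c for c in self.clusters.values()} - set(CLUSTERS) - {"none"})
        if bad:
            raise ConfigurationError(f"unknown cluster labels: {bad}")
        for cl in CLUSTERS:
            if not any(v == cl for v in self.clusters.values()):
                raise ConfigurationError(f"cluster {cl} is empty")

    def channels_in(self, cluster: str) -> list[str]:
        return [ch for ch in self.channel_names if self.clusters[ch] == cluster]

    def cluster_indices(self, names: Sequence[str] | None = None) -> dict[str, np.ndarray]:
        """Channel indices per cluster, in the order of ``names``
        (defaults to the layout's own channel order)."""
        names = list(names) if names is not None else list(self.channel_names)
        out = {}
        for cl in CLUSTERS:
            idx = [i for i, ch in enumerate(names) if self.clusters.get(ch) == cl]
            out[cl] = np.asarray(idx, dtype=int)
        return out


@dataclass
class AnnotationSet:
    """Behavioral annotations: one row per labelled span.

    Columns: ``onset_s``, ``duration_s``, ``condition`` in {BL1,BL2,AO,AE},
    ``trial_index`` (-1 for BL1), ``valid`` in {0,1} and ``hand`` in
    {R,L,NA}.  For AO/AE spans ``onset_s + duration_s`` is the annotated
    button-press instant; the analysis epoch is the 1500 ms before it.
    """

    df: pd.DataFrame

    REQUIRED = ("onset_s", "duration_s", "condition", "trial_index", "valid", "hand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"annotation columns missing: {missing}")
        bad = set(self.df["condition"]) - set(CONDITIONS)
        if bad:
            raise ConfigurationError(f"unknown condition labels: {sorted(bad)}")

    def of(self, condition: str, valid_only: bool = True) -> pd.DataFrame:
        sel = self.df[self.df["condition"] == condition]
        if valid_only:
            sel = sel[sel["valid"] == 1]
        return sel.reset_index(drop=True)


@dataclass
class EpochSet:
    """Condition-labelled fixed-length epochs plus BL1 segments.

    ``epochs`` holds the BL2/AO/AE epochs; BL2 epochs are 2000 ms and AO/AE
    epochs 1500 ms, so the array is ragged across conditions and stored as a
    list of (n_channels, n_samples) arrays.  BL1 is kept separately as a
    list of contiguous valid segments of arbitrary length.
    """

    epochs: list[np.ndarray]
    conditions: list[str]  # per epoch, in {BL2, AO, AE}
    trial_index: list[int]
    hands: list[str]  # per epoch; "NA" outside AE
    bl1_segments: list[np.ndarray]
    sfreq: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.epochs)
        if not (len(self.conditions) == len(self.trial_index) == len(self.hands) == n):
            raise ConfigurationError("epoch metadata lengths disagree")

    def count(self, condition: str) -> int:
        return sum(1 for c in self.conditions if c == condition)

    def indices(self, condition: str) -> np.ndarray:
        return np.asarray([i for i, c in enumerate(self.conditions) if c == condition])

    def select(self, keep: Sequence[int]) -> "EpochSet":
        keep = list(keep)
        return EpochSet(
            epochs=[self.epochs[i] for i in keep],
            conditions=[self.conditions[i] for i in keep],
            trial_index=[self.trial_index[i] for i in keep],
            hands=[self.hands[i] for i in keep],
            bl1_segments=list(self.bl1_segments),
            sfreq=self.sfreq,
            channel_names=list(self.channel_names),
        )


# ---------------------------------------------------------------------------
# Default layout
# ---------------------------------------------------------------------------


def make_default_layout(n_channels: int = 60) -> ChannelLayout:
    """A deterministic 60-channel cap on the upper unit hemisphere.

    Channels are placed on a spiral covering the scalp (z >= 0.05) and
    assigned to the seven clusters by their anterior-posterior (y) and
    lateral (x) coordinates; a narrow midline strip outside the occipital
    region is deliberately left unassigned (cluster "none") so that the
    cluster partition, like a real montage, does not cover the whole cap.
    """

    # Fibonacci spiral restricted to the upper cap, deterministic.
    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n_channels)
    z = 0.08 + (0.999 - 0.08) * (i + 0.5) / n_channels  # heights above equator
    phi = 2 * np.pi * i / golden
    r = np.sqrt(1 - z ** 2)
    x, y = r * np.cos(phi), r * np.sin(phi)  # x: left(-)/right(+), y: post(-)/ant(+)
    pos = np.column_stack([x, y, z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)

    names = [f"E{k + 1}" for k in range(n_channels)]
    clusters: dict[str, str] = {}
    for name, (cx, cy, cz) in zip(names, pos):
        if cy < -0.55:
            cl = "O"
        elif cy > 0.30:
            cl = "none" if abs(cx) < 0.12 else ("F_left" if cx < 0 else "F_right")
        elif cy >= -0.15:
            cl = "none" if abs(cx) < 0.12 else ("C_left" if cx < 0 else "C_right")
        else:
            cl = "none" if abs(cx) < 0.12 else ("P_left" if cx < 0 else "P_right")
        clusters[name] = cl
    return ChannelLayout(names, pos, clusters)


def write_layout_csv(layout: ChannelLayout, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": layout.channel_names,
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
            "z": layout.positions[:, 2],
            "cluster": [layout.clusters[c] for c in layout.channel_names],
        }
    )
    df.to_csv(path, index=False)


def read_layout_csv(path: str | Path) -> ChannelLayout:
    df = pd.read_csv(path)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return ChannelLayout(
        channel_names=list(df["name"].astype(str)),
        positions=pos,
        clusters=dict(zip(df["name"].astype(str), df["cluster"].astype(str))),
    )


# ---------------------------------------------------------------------------
# Annotation CSV I/O
# ---------------------------------------------------------------------------


def write_annotations_csv(ann: AnnotationSet, path: str | Path) -> None:
    ann.df.to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> AnnotationSet:
    df = pd.read_csv(path)
    return AnnotationSet(df)


# ---------------------------------------------------------------------------
# EDF writer / reader
# ---------------------------------------------------------------------------
# A minimal EDF (16-bit) writer: one data record per second, physical units
# uV.  Reading goes through MNE's native EDF reader.


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as plain EDF with 16-bit samples in uV.

    The sampling rate must be an integer (one data record per second).
    Samples are scaled channel-wise to the full digital range, so the
    quantization step is (physical range)/65535.
    """

    if abs(rec.sfreq - round(rec.sfreq)) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    sfreq = int(round(rec.sfreq))
    n_ch = rec.n_channels
    # pad the tail so the signal splits into whole 1 s records
    n_rec = int(np.ceil(rec.n_samples / sfreq))
    data = np.zeros((n_ch, n_rec * sfreq))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = pmax - pmin
    flat = span <= 0
    pmax[flat] = pmin[flat] + 1.0  # avoid zero physical span on flat channels
    dmin, dmax = -32768, 32767

    def _f(text: str, width: int) -> bytes:
        s = text[:width]
        return (s + " " * (width - len(s))).encode("ascii")

    hdr = io.BytesIO()
    hdr.write(_f("0", 8))
    hdr.write(_f("X X X X", 80))  # local patient id (anonymous)
    hdr.write(_f("Startdate X", 80))
    hdr.write(_f("01.01.00", 8))
    hdr.write(_f("00.00.00", 8))
    hdr.write(_f(str(256 * (1 + n_ch)), 8))
    hdr.write(_f("", 44))
    hdr.write(_f(str(n_rec), 8))
    hdr.write(_f("1", 8))  # record duration, s
    hdr.write(_f(str(n_ch), 4))
    for name in rec.channel_names:
        hdr.write(_f(name, 16))
    for _ in range(n_ch):
        hdr.write(_f("AgAgCl electrode", 80))
    for _ in range(n_ch):
        hdr.write(_f("uV", 8))
    for v in pmin:
        hdr.write(_f(f"{v:.6g}"[:8], 8))
    for v in pmax:
        hdr.write(_f(f"{v:.6g}"[:8], 8))
    hdr.write(_f(str(dmin), 8) * n_ch)
    hdr.write(_f(str(dmax), 8) * n_ch)
    for _ in range(n_ch):
        hdr.write(_f("", 80))  # prefiltering
    hdr.write(_f(str(sfreq), 8) * n_ch)
    hdr.write(_f("", 32) * n_ch)

    # re-read the rounded physical limits so reader-side scaling is exact
    pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    gain = (dmax - dmin) / (pmax_r - pmin_r)
    digital = np.rint((data - pmin_r[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for k in range(n_rec):
            chunk = digital[:, k * sfreq : (k + 1) * sfreq]
            fh.write(chunk.tobytes())


def read_edf(path: str | Path, layout: ChannelLayout) -> Recording:
    """Read an EDF file into a :class:`Recording`, geometry from ``layout``."""

    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    names = list(raw.ch_names)
    order = [names.index(ch) for ch in layout.channel_names if ch in names]
    if len(order) != len(layout.channel_names):
        missing = set(layout.channel_names) - set(names)
        raise ConfigurationError(f"EDF is missing layout channels: {sorted(missing)}")
    return Recording(
        data=data[order],
        sfreq=float(raw.info["sfreq"]),
        channel_names=list(layout.channel_names),
        positions=layout.positions.copy(),
    )


# ---------------------------------------------------------------------------
# Small helpers
# ---------------------------------------------------------------------------


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round-half-up to ``ndigits`` decimals (printed-table convention)."""

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
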