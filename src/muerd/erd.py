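"""Event-related desynchronization/synchronization (ERD/ERS).

ERD/ERS = (A - R) / R * 100, where A is the mu-band power of an AO or AE
epoch and R the mean mu-band power of the chosen baseline (BL1: the pooled
30 s Welch estimate; BL2: the mean over all valid BL2 epochs of the
session).  Negative values are desynchronization.  Per-channel values are
averaged within the seven scalp clusters; channels assigned to no cluster
are excluded.

By default "power" is the log-transformed PSD (log10(1 + PSD)), matching
the processing order of the analysis; ``power_scale="raw"`` switches to
untransformed power for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CLUSTERS, ChannelLayout, ConfigurationError, PipelineConfig
from .spectral import MuBand, SpectrumSet

__all__ = [
    "ErdTable",
    "HandUsage",
    "band_power",
    "baseline_band_power",
    "cluster_average",
    "compute_erd",
    "compute_erd_table",
    "lateralized_score",
]


@dataclass
class HandUsage:
    n_right: int
    n_left: int

    @classmethod
    def from_hands(cls, hands) -> "HandUsage":
        return cls(n_right=sum(1 for h in hands if h == "R"),
                   n_left=sum(1 for h in hands if h == "L"))


def lateralized_score(h: HandUsage) -> float:
    """(%Right - %Left) / (%Right + %Left) in [-1, 1]; positive = right
    preference."""
    n = h.n_right + h.n_left
    if n < 1:
        raise ConfigurationError("lateralized score needs at least one AE trial")
    return (h.n_right - h.n_left) / n


@dataclass
class ErdTable:
    """Per-epoch, per-cluster ERD/ERS (%) for each (condition, baseline).

    ``values[(condition, baseline)]`` is an (n_epochs, 7) array in the
    cluster order of :data:`muerd.core.CLUSTERS`; the epoch axis is shared
    between the two baselines of a condition (same event epochs, different
    reference), which is what the paired statistics rely on.
    """

    values: dict[tuple[str, str], np.ndarray]
    clusters: tuple[str, ...] = CLUSTERS

    def epoch_count(self, condition: str) -> int:
        for (cond, _), arr in self.values.items():
            if cond == condition:
                return arr.shape[0]
        return 0

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        rows = []
        for (cond, base), arr in sorted(self.values.items()):
            for e in range(arr.shape[0]):
                for c, cl in enumerate(self.clusters):
                    rows.append((subject_id, cond, base, e, cl, arr[e, c]))
        return pd.DataFrame(
            rows,
            columns=["subject", "condition", "baseline", "epoch", "cluster",
                     "erd_percent"],
        )


def _band_mask(ss: SpectrumSet, band: MuBand) -> np.ndarray:
    mask = (ss.freqs >= band.lo) & (ss.freqs <= band.hi)
    if mask.sum() != 3:
        raise ConfigurationError(
            f"band {band.lo}-{band.hi} Hz does not map to 3 bins of the grid"
        )
    return mask


def _to_scale(logpsd: np.ndarray, power_scale: str) -> np.ndarray:
    if power_scale == "log1p":
        return logpsd
    if power_scale == "raw":
        return 10.0 ** logpsd - 1.0
    raise ConfigurationError(f"unknown power_scale {power_scale!r}")


def band_power(ss: SpectrumSet, band: MuBand, power_scale: str = "log1p") -> np.ndarray:
    """Mean power over the band's 3 bins, per epoch and channel."""
    mask = _band_mask(ss, band)
    return _to_scale(ss.psd, power_scale)[:, :, mask].mean(axis=2)


def baseline_band_power(ss: SpectrumSet, band: MuBand, baseline: str,
                        power_scale: str = "log1p") -> np.ndarray:
    """Reference power R per channel: the session mean of the baseline's
    band power (all BL2 epochs, or the pooled BL1 Welch estimate)."""
    mask = _band_mask(ss, band)
    if baseline == "BL1":
        return _to_scale(ss.bl1_logpsd, power_scale)[:, mask].mean(axis=1)
    bp = band_power(ss, band, power_scale)
    idx = ss.indices("BL2")
    if len(idx) == 0:
        raise ConfigurationError("no BL2 epochs to build the reference from")
    return bp[idx].mean(axis=0)


def compute_erd(event_power: np.ndarray, baseline_mean_power: np.ndarray) -> np.ndarray:
    """(A - R) / R * 100; requires strictly positive reference power."""
    A = np.asarray(event_power, dtype=float)
    R = np.asarray(baseline_mean_power, dtype=float)
    if np.any(R <= 0):
        raise ConfigurationError("baseline power must be > 0 to normalize ERD")
    return (A - R) / R * 100.0


def cluster_average(per_channel: np.ndarray, layout: ChannelLayout,
                    channel_names) -> np.ndarray:
    """Unweighted mean of per-channel values within each of the 7 clusters.

    ``per_channel`` is (..., n_channels); returns (..., 7) in CLUSTERS
    order.  Raises when a cluster has no channels in ``channel_names``.
    """
    idx = layout.cluster_indices(channel_names)
    cols = []
    for cl in CLUSTERS:
        if len(idx[cl]) == 0:
            raise ConfigurationError(f"cluster {cl} has no channels after QC")
        cols.append(np.asarray(per_channel)[..., idx[cl]].mean(axis=-1))
    return np.stack(cols, axis=-1)


def compute_erd_table(
    ss: SpectrumSet,
    bands: dict[str, MuBand],
    layout: ChannelLayout,
    cfg: PipelineConfig | None = None,
) -> ErdTable:
    """Full ERD table: every AO/AE epoch scored against both baselines with
    that baseline's personalized band, then cluster-averaged."""
    cfg = cfg or PipelineConfig()
    values: dict[tuple[str, str], np.ndarray] = {}
    for baseline, band in bands.items():
        bp = band_power(ss, band, cfg.power_scale)
        R = baseline_band_power(ss, band, baseline, cfg.power_scale)
        for cond in ("AO", "AE"):
            idx = ss.indices(cond)
            erd_ch = compute_erd(bp[idx], R[None, :])
            values[(cond, baseline)] = cluster_average(erd_ch, layout,
                                                       ss.channel_names)
    return ErdTable(values=values)
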