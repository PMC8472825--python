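"""Per-epoch Welch spectra and personalized mu-band selection.

Power spectral density is estimated per epoch and channel with Welch's
method (250-sample Hamming windows, 125-sample overlap; at 250 Hz this
gives a 1 Hz frequency grid) and log-transformed as log10(1 + PSD).  The
subject's mu band is the 3 Hz band centred on the frequency in 4-13 Hz most
attenuated during action execution relative to a baseline, averaged across
channels -- toddler mu peaks vary with age, so a fixed band would mix
subjects' rhythms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import median_abs_deviation

from .core import ConfigurationError, EpochSet, InsufficientDataError, PipelineConfig

__all__ = ["MuBand", "SpectrumSet", "find_mu_band", "outlier_screen", "welch_log_psd"]


@dataclass
class SpectrumSet:
    """Log-PSD per epoch and channel on a fixed 1 Hz frequency grid.

    ``psd`` covers the fixed-length BL2/AO/AE epochs; BL1 is a single Welch
    estimate pooled over all its segments (windows never straddle segment
    boundaries), stored in ``bl1_logpsd``.
    """

    psd: np.ndarray  # (n_epochs, n_channels, n_freqs), log10(1 + PSD)
    freqs: np.ndarray  # Hz
    conditions: list[str]
    channel_names: list[str]
    bl1_logpsd: np.ndarray | None  # (n_channels, n_freqs)
    bl1_n_windows: int
    hands: list[str]

    def indices(self, condition: str) -> np.ndarray:
        return np.asarray([i for i, c in enumerate(self.conditions) if c == condition])

    def mean_logpsd(self, condition: str) -> np.ndarray:
        """Mean log-PSD over a condition's epochs, (n_channels, n_freqs)."""
        if condition == "BL1":
            if self.bl1_logpsd is None:
                raise InsufficientDataError("no BL1 spectrum available")
            return self.bl1_logpsd
        idx = self.indices(condition)
        if len(idx) == 0:
            raise InsufficientDataError(f"no {condition} epochs")
        return self.psd[idx].mean(axis=0)

    def select(self, keep) -> "SpectrumSet":
        keep = list(keep)
        return SpectrumSet(
            psd=self.psd[keep],
            freqs=self.freqs,
            conditions=[self.conditions[i] for i in keep],
            channel_names=list(self.channel_names),
            bl1_logpsd=self.bl1_logpsd,
            bl1_n_windows=self.bl1_n_windows,
            hands=[self.hands[i] for i in keep],
        )

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        """Long-format export: subject, epoch, channel, freq, logpsd."""
        n_ep, n_ch, n_f = self.psd.shape
        ep, ch, fr = np.meshgrid(np.arange(n_ep), np.arange(n_ch),
                                 np.arange(n_f), indexing="ij")
        return pd.DataFrame(
            {
                "subject": subject_id,
                "epoch": ep.ravel(),
                "condition": [self.conditions[i] for i in ep.ravel()],
                "channel": [self.channel_names[i] for i in ch.ravel()],
                "freq": self.freqs[fr.ravel()],
                "logpsd": self.psd.ravel(),
            }
        )


@dataclass
class MuBand:
    """Personalized 3 Hz mu band (3 bins on the 1 Hz grid)."""

    center: int  # Hz
    lo: int
    hi: int
    baseline_used: str  # "BL1" or "BL2"
    no_attenuation: bool = False

    def __post_init__(self) -> None:
        if self.hi - self.lo != 2:
            raise ConfigurationError("mu band must span 3 bins (hi - lo = 2)")
        if self.lo < 4 or self.hi > 13:
            raise ConfigurationError("mu band must stay within 4-13 Hz")


def _welch(x: np.ndarray, sfreq: float, nperseg: int, noverlap: int):
    """Welch PSD along the last axis; uV^2/Hz, no detrending."""
    return signal.welch(
        x, fs=sfreq, window="hamming", nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="density", axis=-1,
    )


def _n_windows(n: int, nperseg: int, step: int) -> int:
    return 0 if n < nperseg else (n - nperseg) // step + 1


def welch_log_psd(es: EpochSet, cfg: PipelineConfig | None = None) -> SpectrumSet:
    """Welch log-PSD for every epoch plus the pooled BL1 estimate.

    BL2 epochs (500 samples) average 3 windows, AO/AE epochs (375 samples)
    2 windows; BL1 segments contribute as many windows as fit and are
    pooled into a single estimate weighted by window count.
    """
    cfg = cfg or PipelineConfig()
    nps, nov = cfg.welch_nperseg, cfg.welch_noverlap
    step = nps - nov

    psds = []
    freqs = None
    for i, ep in enumerate(es.epochs):
        if ep.shape[1] < nps:
            raise InsufficientDataError(
                f"epoch {i} ({es.conditions[i]}) shorter than one Welch window"
            )
        freqs, p = _welch(ep, es.sfreq, nps, nov)
        psds.append(np.log10(1.0 + p))
    n_ch = len(es.channel_names)
    if freqs is None:
        freqs = np.fft.rfftfreq(nps, d=1.0 / es.sfreq)
    psd = (np.stack(psds) if psds
           else np.zeros((0, n_ch, len(freqs))))

    bl1_logpsd = None
    bl1_nw = 0
    acc = None
    for seg in es.bl1_segments:
        nw = _n_windows(seg.shape[1], nps, step)
        if nw == 0:
            continue
        _, p = _welch(seg, es.sfreq, nps, nov)
        acc = p * nw if acc is None else acc + p * nw
        bl1_nw += nw
    if acc is not None:
        bl1_logpsd = np.log10(1.0 + acc / bl1_nw)

    return SpectrumSet(
        psd=psd,
        freqs=np.asarray(freqs),
        conditions=list(es.conditions),
        channel_names=list(es.channel_names),
        bl1_logpsd=bl1_logpsd,
        bl1_n_windows=bl1_nw,
        hands=list(es.hands),
    )


def outlier_screen(ss: SpectrumSet, cfg: PipelineConfig | None = None) -> list[int]:
    """Flag epochs whose broadband (4-13 Hz) log-power is more than 3
    scaled MADs from their condition's median.

    The comparison is strict, so an epoch exactly at the boundary is kept;
    with a zero MAD (perfectly homogeneous condition) nothing is flagged.
    """
    cfg = cfg or PipelineConfig()
    band = (ss.freqs >= cfg.mu_search_lo_hz) & (ss.freqs <= cfg.mu_search_hi_hz)
    score = ss.psd[:, :, band].sum(axis=2).mean(axis=1)  # per-epoch scalar
    flagged = []
    for cond in ("BL2", "AO", "AE"):
        idx = ss.indices(cond)
        if len(idx) < 5:
            continue
        med = np.median(score[idx])
        mad = median_abs_deviation(score[idx], scale="normal")
        if mad == 0:
            continue
        for i in idx:
            if abs(score[i] - med) > cfg.outlier_mads * mad:
                flagged.append(int(i))
    return sorted(flagged)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def find_mu_band(
    ss: SpectrumSet,
    baseline: str,
    cfg: PipelineConfig | None = None,
    power_scale: str | None = None,
) -> MuBand:
    """Personalized mu band: per channel, the 4-13 Hz frequency maximizing
    (baseline log-PSD - AE log-PSD); channel values are averaged, rounded
    half-up to an integer and clamped so the +/-1 Hz band stays in 4-13 Hz.

    Per-channel ties break toward the lowest frequency.  When no channel
    shows any attenuation the band is still returned, with
    ``no_attenuation`` set.
    """
    cfg = cfg or PipelineConfig()
    if baseline not in ("BL1", "BL2"):
        raise ConfigurationError(f"baseline must be BL1 or BL2, got {baseline!r}")
    ae_idx = ss.indices("AE")
    if len(ae_idx) < 5:
        raise InsufficientDataError(f"need >= 5 AE epochs, have {len(ae_idx)}")

    base = ss.mean_logpsd(baseline)
    ae = ss.psd[ae_idx].mean(axis=0)
    scale = power_scale or cfg.power_scale
    if scale == "raw":
        base = 10.0 ** base - 1.0
        ae = 10.0 ** ae - 1.0

    band = (ss.freqs >= cfg.mu_search_lo_hz) & (ss.freqs <= cfg.mu_search_hi_hz)
    grid = ss.freqs[band]
    diff = (base - ae)[:, band]  # attenuation, per channel x freq
    per_channel = grid[np.argmax(diff, axis=1)]  # argmax ties -> lowest freq
    center = _round_half_up(float(per_channel.mean()))
    lo_c = int(cfg.mu_search_lo_hz) + 1
    hi_c = int(cfg.mu_search_hi_hz) - 1
    center = min(max(center, lo_c), hi_c)
    return MuBand(
        center=center,
        lo=center - 1,
        hi=center + 1,
        baseline_used=baseline,
        no_attenuation=bool((diff <= 0).all()),
    )
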