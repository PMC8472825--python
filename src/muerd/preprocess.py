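"""Continuous-EEG cleaning and epoching.

Fixed stage order: band-pass filter -> bad-channel detection/interpolation
-> contaminated-window rejection -> average reference -> segmentation ->
artifact-epoch rejection.  Channel count and order are preserved
end-to-end; only epochs/time are ever removed.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (
    AnnotationSet,
    ChannelLayout,
    ConfigurationError,
    EpochSet,
    InsufficientDataError,
    PipelineConfig,
    QualityError,
    Recording,
)

__all__ = [
    "average_reference",
    "bandpass_filter",
    "detect_bad_channels",
    "insufficient_conditions",
    "interpolate_channels",
    "reject_artifact_epochs",
    "reject_contaminated_windows",
    "segment_epochs",
    "spline_interpolation_matrix",
]

logger = logging.getLogger("muerd")

_FIR_HP_TRANS_HZ = 1.0
_FIR_LP_TRANS_HZ = 5.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def bandpass_filter(rec: Recording, hp: float = 1.0, lp: float = 45.0) -> Recording:
    """Zero-phase windowed-sinc (Hamming) FIR band-pass.

    Transition bandwidths are 1 Hz (high-pass side) and 5 Hz (low-pass
    side).  Raises :class:`InsufficientDataError` when the recording is
    shorter than three filter lengths.
    """
    import mne

    if not hp < lp < rec.sfreq / 2:
        raise ConfigurationError(f"need hp < lp < Nyquist, got {hp}, {lp}")
    # Hamming window: ~3.3 / transition-bandwidth seconds of kernel
    filt_len = int(round(3.3 / min(_FIR_HP_TRANS_HZ, _FIR_LP_TRANS_HZ) * rec.sfreq))
    if rec.n_samples < 3 * filt_len:
        raise InsufficientDataError(
            f"recording of {rec.n_samples} samples shorter than 3 filter "
            f"lengths ({3 * filt_len})"
        )
    filtered = mne.filter.filter_data(
        rec.data,
        sfreq=rec.sfreq,
        l_freq=hp,
        h_freq=lp,
        l_trans_bandwidth=_FIR_HP_TRANS_HZ,
        h_trans_bandwidth=_FIR_LP_TRANS_HZ,
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )
    out = rec.copy()
    out.data = filtered
    return out


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin et al. style)
# ---------------------------------------------------------------------------

_SPLINE_M = 4
_SPLINE_TERMS = 7
_SPLINE_REG = 1e-5


def _g_matrix(cosang: np.ndarray) -> np.ndarray:
    """Spline kernel g(cos) = 1/(4*pi) * sum_n (2n+1)/(n(n+1))^m P_n(cos)."""
    coefs = np.zeros(_SPLINE_TERMS + 1)
    for n in range(1, _SPLINE_TERMS + 1):
        coefs[n] = (2 * n + 1) / (n * (n + 1)) ** _SPLINE_M
    return np.polynomial.legendre.legval(np.clip(cosang, -1, 1), coefs) / (4 * np.pi)


def spline_interpolation_matrix(good_pos: np.ndarray, bad_pos: np.ndarray) -> np.ndarray:
    """Linear operator mapping good-channel values to spline estimates at
    the bad-channel sites; includes the constant term, so spatially
    constant fields are reproduced exactly."""
    good_pos = np.asarray(good_pos, float)
    bad_pos = np.asarray(bad_pos, float)
    k = len(good_pos)
    G = _g_matrix(good_pos @ good_pos.T) + _SPLINE_REG * np.eye(k)
    Gb = _g_matrix(bad_pos @ good_pos.T)
    # augmented system enforcing sum(c) = 0 with an intercept term
    M = np.zeros((k + 1, k + 1))
    M[:k, :k] = G
    M[:k, k] = 1.0
    M[k, :k] = 1.0
    Minv = np.linalg.inv(M)
    A = np.hstack([Gb, np.ones((len(bad_pos), 1))]) @ Minv[:, :k]
    return A


# ---------------------------------------------------------------------------
# bad channels
# ---------------------------------------------------------------------------


def _flat_channels(rec: Recording, flat_s: float) -> list[int]:
    limit = int(flat_s * rec.sfreq)
    out = []
    step = np.abs(np.diff(rec.data, axis=1)) < 1e-10
    for ch in range(rec.n_channels):
        run = best = 0
        for v in step[ch]:
            run = run + 1 if v else 0
            if run > best:
                best = run
        if best + 1 > limit:
            out.append(ch)
    return out


def _reconstruction_matrix(rec: Recording, exclude: set[int]) -> np.ndarray:
    """Row i: spline estimate of channel i from all other trusted channels
    (channels in ``exclude`` are never used as predictors)."""
    n = rec.n_channels
    R = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        others = idx[(idx != i) & ~np.isin(idx, list(exclude - {i}))]
        A = spline_interpolation_matrix(rec.positions[others], rec.positions[[i]])
        R[i, others] = A[0]
    return R


def detect_bad_channels(
    rec: Recording,
    flat_s: float = 5.0,
    corr_thresh: float = 0.85,
    corr_window_s: float = 5.0,
    bad_window_fraction: float = 0.4,
    max_bad_fraction: float = 0.15,
) -> list[int]:
    """Flat-line and low-correlation bad-channel detection.

    A channel is bad when it is flat for longer than ``flat_s`` seconds, or
    when its correlation with its spherical-spline reconstruction from the
    other channels drops below ``corr_thresh`` in more than
    ``bad_window_fraction`` of ``corr_window_s``-long windows.  Detection
    is iterated with already-flagged channels removed from the
    reconstructions, so one noisy electrode cannot drag its neighbours
    below threshold.  Raises :class:`QualityError` when more than
    ``max_bad_fraction`` of channels are flagged.
    """
    if rec.n_channels < 8:
        raise ConfigurationError("bad-channel detection needs >= 8 channels")
    flat = set(_flat_channels(rec, flat_s))

    w = int(corr_window_s * rec.sfreq)
    n_win = rec.n_samples // w
    if n_win == 0:
        raise InsufficientDataError("recording shorter than one correlation window")
    x = rec.data[:, : n_win * w].reshape(rec.n_channels, n_win, w)
    x = x - x.mean(axis=2, keepdims=True)

    def lowcorr_pass(exclude: set[int]) -> set[int]:
        recon = _reconstruction_matrix(rec, exclude) @ rec.data
        y = recon[:, : n_win * w].reshape(rec.n_channels, n_win, w)
        y = y - y.mean(axis=2, keepdims=True)
        num = (x * y).sum(axis=2)
        den = np.sqrt((x ** 2).sum(axis=2) * (y ** 2).sum(axis=2))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
        frac_bad = (corr < corr_thresh).mean(axis=1)
        return set(np.nonzero(frac_bad > bad_window_fraction)[0].tolist())

    lowcorr: set[int] = set()
    for _ in range(3):  # iterate to a fixed point, suspects excluded
        new = lowcorr_pass(flat | lowcorr)
        if new == lowcorr:
            break
        lowcorr = new

    bad = sorted(flat | lowcorr)
    if len(bad) > max_bad_fraction * rec.n_channels:
        raise QualityError(
            f"{len(bad)}/{rec.n_channels} channels flagged bad "
            f"(limit {max_bad_fraction:.0%})"
        )
    return bad


def interpolate_channels(rec: Recording, bad: list[int]) -> Recording:
    """Replace bad-channel signals by spherical-spline estimates from the
    good channels; good channels are untouched."""
    if not bad:
        return rec.copy()
    bad = sorted(set(bad))
    if len(bad) >= rec.n_channels:
        raise QualityError("all channels bad; nothing to interpolate from")
    if len(bad) > 0.15 * rec.n_channels:
        raise QualityError(f"refusing to interpolate {len(bad)} channels (> 15%)")
    good = [i for i in range(rec.n_channels) if i not in bad]
    A = spline_interpolation_matrix(rec.positions[good], rec.positions[bad])
    out = rec.copy()
    out.data[bad] = A @ rec.data[good]
    return out


# ---------------------------------------------------------------------------
# continuous-window rejection and referencing
# ---------------------------------------------------------------------------


def reject_contaminated_windows(
    rec: Recording,
    window_s: float = 1.0,
    chan_fraction: float = 0.5,
    amp_thresh: float = 200.0,
) -> tuple[Recording, np.ndarray]:
    """Mark windows in which more than ``chan_fraction`` of channels exceed
    ``amp_thresh`` uV peak-to-peak.

    Returns the recording (data untouched) and a boolean kept-time mask per
    sample; segmentation later skips epochs that touch rejected samples.
    """
    w = int(window_s * rec.sfreq)
    if rec.n_samples <= w:
        raise InsufficientDataError("recording not longer than one rejection window")
    keep = np.ones(rec.n_samples, dtype=bool)
    for a in range(0, rec.n_samples, w):
        b = min(a + w, rec.n_samples)
        ptp = rec.data[:, a:b].max(axis=1) - rec.data[:, a:b].min(axis=1)
        if (ptp > amp_thresh).mean() > chan_fraction:
            keep[a:b] = False
    if not keep.any():
        raise QualityError("all data rejected by the contaminated-window rule")
    rejected_s = (~keep).sum() / rec.sfreq
    if rejected_s:
        logger.info("window rejection removed %.1f s", rejected_s)
    return rec, keep


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average (per-sample channel mean -> 0)."""
    if rec.n_channels < 2:
        raise ConfigurationError("average reference needs >= 2 channels")
    out = rec.copy()
    out.data = out.data - out.data.mean(axis=0, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_epochs(
    rec: Recording,
    ann: AnnotationSet,
    keep_mask: np.ndarray | None = None,
    cfg: PipelineConfig | None = None,
) -> EpochSet:
    """Cut condition epochs out of kept time.

    BL2 epochs run [onset, onset + 2 s); AO/AE epochs are the 1500 ms
    before the annotated button press (= span end), i.e. [end - 1.5 s,
    end).  BL1 is returned as contiguous kept segments totalling at most
    30 s.  Epochs marked invalid or touching rejected time are dropped
    (logged, not an error).
    """
    cfg = cfg or PipelineConfig()
    sf = rec.sfreq
    if keep_mask is None:
        keep_mask = np.ones(rec.n_samples, dtype=bool)

    epochs, conds, trials, hands = [], [], [], []
    for _, row in ann.df.iterrows():
        cond = row["condition"]
        if cond == "BL1":
            continue
        if cond == "BL2":
            a = int(round(row["onset_s"] * sf))
            b = a + int(round(cfg.bl2_len_s * sf))
        else:  # AO / AE end at the button press
            b = int(round((row["onset_s"] + row["duration_s"]) * sf))
            a = b - int(round(cfg.event_len_s * sf))
        if row["valid"] != 1:
            logger.info("dropping %s trial %s: marked invalid", cond, row["trial_index"])
            continue
        if a < 0 or b > rec.n_samples:
            logger.info("dropping %s trial %s: outside recording", cond, row["trial_index"])
            continue
        if not keep_mask[a:b].all():
            logger.info("dropping %s trial %s: crosses rejected window",
                        cond, row["trial_index"])
            continue
        epochs.append(rec.data[:, a:b].copy())
        conds.append(cond)
        trials.append(int(row["trial_index"]))
        hands.append(str(row["hand"]) if cond == "AE" else "NA")

    # BL1: contiguous kept runs inside valid BL1 annotation spans
    bl1_segments: list[np.ndarray] = []
    budget = int(round(cfg.bl1_len_s * sf))
    for _, row in ann.of("BL1").iterrows():
        a = int(round(row["onset_s"] * sf))
        b = min(int(round((row["onset_s"] + row["duration_s"]) * sf)), rec.n_samples)
        i = a
        while i < b and budget > 0:
            if not keep_mask[i]:
                i += 1
                continue
            j = i
            while j < b and keep_mask[j]:
                j += 1
            seg = rec.data[:, i : min(j, i + budget)].copy()
            budget -= seg.shape[1]
            bl1_segments.append(seg)
            i = j
    return EpochSet(
        epochs=epochs,
        conditions=conds,
        trial_index=trials,
        hands=hands,
        bl1_segments=bl1_segments,
        sfreq=sf,
        channel_names=list(rec.channel_names),
    )


# ---------------------------------------------------------------------------
# epoch-level artifact rejection
# ---------------------------------------------------------------------------


def reject_artifact_epochs(es: EpochSet, amp_thresh: float = 200.0) -> EpochSet:
    """Drop epochs (and BL1 segments) containing any sample above
    ``amp_thresh`` uV in absolute value on any channel."""
    keep = [i for i, ep in enumerate(es.epochs) if np.abs(ep).max() <= amp_thresh]
    dropped = len(es.epochs) - len(keep)
    out = es.select(keep)
    out.bl1_segments = [s for s in es.bl1_segments if np.abs(s).max() <= amp_thresh]
    if dropped or len(out.bl1_segments) < len(es.bl1_segments):
        logger.info(
            "amplitude rejection removed %d epochs and %d BL1 segments",
            dropped, len(es.bl1_segments) - len(out.bl1_segments),
        )
    return out


def insufficient_conditions(es: EpochSet, min_epochs: int = 5) -> list[str]:
    """Conditions with fewer than ``min_epochs`` surviving epochs (BL1
    counts as insufficient when no segment holds a full Welch window)."""
    lacking = [c for c in ("BL2", "AO", "AE") if es.count(c) < min_epochs]
    if not any(s.shape[1] >= 250 for s in es.bl1_segments):
        lacking.append("BL1")
    return lacking
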