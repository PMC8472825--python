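import numpy as np
import pytest
from scipy.signal import get_window

from muerd import EpochSet, MuBand, SpectrumSet, find_mu_band, outlier_screen, welch_log_psd
from muerd.core import ConfigurationError, InsufficientDataError


def _epochset(epochs, conditions, bl1=None, sfreq=250.0, n_ch=None):
    n_ch = n_ch if n_ch is not None else epochs[0].shape[0]
    return EpochSet(
        epochs=list(epochs),
        conditions=list(conditions),
        trial_index=list(range(len(epochs))),
        hands=["R" if c == "AE" else "NA" for c in conditions],
        bl1_segments=list(bl1 or []),
        sfreq=sfreq,
        channel_names=[f"E{i + 1}" for i in range(n_ch)],
    )


def _spectrumset(psd, freqs, conditions, bl1_logpsd=None):
    psd = np.asarray(psd, float)
    return SpectrumSet(
        psd=psd,
        freqs=np.asarray(freqs, float),
        conditions=list(conditions),
        channel_names=[f"E{i + 1}" for i in range(psd.shape[1])],
        bl1_logpsd=None if bl1_logpsd is None else np.asarray(bl1_logpsd, float),
        bl1_n_windows=0 if bl1_logpsd is None else 10,
        hands=["NA"] * len(conditions),
    )


def oracle_welch(x, fs=250.0, nperseg=250, noverlap=125):
    """Mean of Hamming-tapered modified periodograms (density scaling)."""
    w = get_window("hamming", nperseg)
    step = nperseg - noverlap
    periodograms = []
    for a in range(0, len(x) - nperseg + 1, step):
        seg = x[a : a + nperseg] * w
        spec = np.abs(np.fft.rfft(seg)) ** 2 / (fs * np.sum(w ** 2))
        spec[1:-1] *= 2  # one-sided
        periodograms.append(spec)
    return np.fft.rfftfreq(nperseg, 1 / fs), np.mean(periodograms, axis=0)


class TestWelch:
    def test_equals_mean_of_modified_periodograms(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        es = _epochset([x[None, :]], ["BL2"])
        ss = welch_log_psd(es)
        raw = 10.0 ** ss.psd[0, 0] - 1.0
        _, expected = oracle_welch(x)
        assert np.allclose(raw, expected, rtol=1e-10, atol=1e-12)

    def test_pure_tone_power(self):
        a = 4.0
        t = np.arange(500) / 250.0
        x = a * np.sin(2 * np.pi * 7 * t)
        es = _epochset([x[None, :]], ["BL2"])
        ss = welch_log_psd(es)
        raw = 10.0 ** ss.psd[0, 0] - 1.0
        assert ss.freqs[np.argmax(raw)] == 7.0
        # integrated PSD recovers the sinusoid's power a^2/2 (df = 1 Hz)
        assert raw.sum() * 1.0 == pytest.approx(a ** 2 / 2, rel=0.01)

    def test_white_noise_level(self):
        rng = np.random.default_rng(1)
        sigma = 3.0
        es = _epochset([sigma * rng.normal(size=(1, 500)) for _ in range(200)],
                       ["BL2"] * 200)
        ss = welch_log_psd(es)
        raw = (10.0 ** ss.psd - 1.0).mean(axis=0)[0]
        level = raw[2:-2].mean()  # away from the halved edge bins
        assert level == pytest.approx(sigma ** 2 / (250.0 / 2), rel=0.05)

    def test_zero_epoch_zero_spectrum(self):
        es = _epochset([np.zeros((2, 500))], ["BL2"])
        ss = welch_log_psd(es)
        assert np.all(ss.psd == 0.0)

    def test_short_epoch_raises(self):
        es = _epochset([np.zeros((1, 100))], ["BL2"])
        with pytest.raises(InsufficientDataError):
            welch_log_psd(es)

    def test_bl1_pooled_weighting(self):
        """The BL1 estimate is the window-count-weighted pool of its
        segments: identical to Welch on one contiguous run of windows."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 1000))
        pooled = welch_log_psd(_epochset([], [], bl1=[x], n_ch=1))
        # same windows delivered as two abutting segments of whole windows
        split = welch_log_psd(_epochset([], [], bl1=[x[:, :500], x[:, 500:]], n_ch=1))
        assert pooled.bl1_n_windows == 7
        assert split.bl1_n_windows == 6  # windows never straddle the split
        raw_pool = 10.0 ** pooled.bl1_logpsd - 1
        a = 10.0 ** welch_log_psd(_epochset([], [], bl1=[x[:, :500]], n_ch=1)).bl1_logpsd - 1
        b = 10.0 ** welch_log_psd(_epochset([], [], bl1=[x[:, 500:]], n_ch=1)).bl1_logpsd - 1
        assert np.allclose(10.0 ** split.bl1_logpsd - 1, (a + b) / 2, rtol=1e-10)
        assert raw_pool.shape == (1, 126)


class TestOutlierScreen:
    def test_matches_manual_mad_rule(self):
        from scipy.stats import median_abs_deviation

        rng = np.random.default_rng(3)
        for trial in range(5):
            psd = rng.uniform(0.1, 1.0, size=(12, 3, 126))
            if trial % 2:
                psd[0] *= 10.0  # gross power outlier
            ss = _spectrumset(psd, np.arange(126), ["AE"] * 12)
            score = psd[:, :, 4:14].sum(axis=2).mean(axis=1)
            med, mad = np.median(score), median_abs_deviation(score, scale="normal")
            manual = [i for i in range(12) if abs(score[i] - med) > 3 * mad]
            assert outlier_screen(ss) == manual

    def test_homogeneous_epochs_unflagged(self):
        psd = np.full((8, 2, 126), 0.5)
        ss = _spectrumset(psd, np.arange(126), ["AE"] * 8)
        assert outlier_screen(ss) == []

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(4)
        psd = rng.uniform(0.4, 0.6, size=(10, 2, 126))
        psd[7] *= 10
        ss = _spectrumset(psd, np.arange(126), ["AE"] * 10)
        assert outlier_screen(ss) == [7]


class TestMuBand:
    def _bump_psd(self, centers, n_freq=126, depth=1.0):
        """AE spectra attenuated at per-channel centre frequencies."""
        n_ch = len(centers)
        base = np.full((n_ch, n_freq), 2.0)
        ae = base.copy()
        for c, f in enumerate(centers):
            ae[c, f] -= depth
        return base, ae

    def test_recovers_suppressed_frequency(self):
        base, ae = self._bump_psd([7] * 6)
        ss = _spectrumset(np.stack([ae] * 5), np.arange(126), ["AE"] * 5,
                          bl1_logpsd=base)
        band = find_mu_band(ss, "BL1")
        assert (band.lo, band.center, band.hi) == (6, 7, 8)
        assert not band.no_attenuation

    def test_channel_average_rounding(self):
        base, ae = self._bump_psd([6, 6, 6, 8, 8, 8])
        ss = _spectrumset(np.stack([ae] * 5), np.arange(126), ["AE"] * 5,
                          bl1_logpsd=base)
        assert find_mu_band(ss, "BL1").center == 7

    def test_flat_difference_warns_and_breaks_ties_low(self):
        base = np.full((4, 126), 2.0)
        ss = _spectrumset(np.stack([base] * 5), np.arange(126), ["AE"] * 5,
                          bl1_logpsd=base)
        band = find_mu_band(ss, "BL1")
        assert band.no_attenuation
        # argmax of an all-zero difference is the lowest frequency (4 Hz),
        # clamped so the 3-bin band fits the 4-13 Hz range
        assert (band.lo, band.center, band.hi) == (4, 5, 6)

    def test_needs_five_ae_epochs(self):
        base, ae = self._bump_psd([7] * 3)
        ss = _spectrumset(np.stack([ae] * 4), np.arange(126), ["AE"] * 4,
                          bl1_logpsd=base)
        with pytest.raises(InsufficientDataError):
            find_mu_band(ss, "BL1")

    def test_band_shape_validation(self):
        with pytest.raises(ConfigurationError):
            MuBand(center=7, lo=5, hi=9, baseline_used="BL1")
        with pytest.raises(ConfigurationError):
            MuBand(center=13, lo=12, hi=14, baseline_used="BL1")
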