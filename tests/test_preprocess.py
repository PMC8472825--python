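import numpy as np
import pandas as pd
import pytest

from conftest import simple_recording
from muerd import AnnotationSet, PipelineConfig, SubjectScenario, generate_subject
from muerd.core import ConfigurationError, InsufficientDataError, QualityError
from muerd.preprocess import (
    average_reference,
    bandpass_filter,
    detect_bad_channels,
    insufficient_conditions,
    interpolate_channels,
    reject_artifact_epochs,
    reject_contaminated_windows,
    segment_epochs,
    spline_interpolation_matrix,
)


def _sine_rec(layout, freqs_amps, n_ch=8, dur_s=60.0, sfreq=250.0, dc=0.0):
    t = np.arange(int(dur_s * sfreq)) / sfreq
    x = dc + sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    return simple_recording(np.tile(x, (n_ch, 1)), layout, sfreq)


class TestFilter:
    def test_passband_and_stopband(self, layout):
        rec = _sine_rec(layout, [(10.0, 10.0), (60.0, 10.0)], dc=100.0)
        out = bandpass_filter(rec)
        mid = slice(5000, 10000)  # away from edges
        t = np.arange(rec.n_samples)[mid] / rec.sfreq
        amp10 = 2 * np.abs(np.mean(out.data[0, mid] * np.exp(-2j * np.pi * 10 * t)))
        amp60 = 2 * np.abs(np.mean(out.data[0, mid] * np.exp(-2j * np.pi * 60 * t)))
        assert amp10 == pytest.approx(10.0, rel=0.05)  # passband preserved
        assert amp60 < 10.0 * 10 ** (-20 / 20)  # >= 20 dB down
        assert abs(out.data[0, mid].mean()) < 1.0  # DC removed

    def test_short_recording_raises(self, layout):
        rec = _sine_rec(layout, [(10.0, 1.0)], dur_s=2.0)
        with pytest.raises(InsufficientDataError):
            bandpass_filter(rec)

    def test_bad_corners_raise(self, layout):
        rec = _sine_rec(layout, [(10.0, 1.0)])
        with pytest.raises(ConfigurationError):
            bandpass_filter(rec, hp=50.0, lp=45.0)


class TestSphericalSpline:
    def test_constant_field_reproduced_exactly(self, layout):
        pos = layout.positions
        A = spline_interpolation_matrix(pos[1:], pos[:1])
        est = A @ np.full(len(pos) - 1, 7.3)
        assert est[0] == pytest.approx(7.3, abs=1e-9)

    def test_dipolar_field_leave_one_out(self, layout):
        """A smooth dipolar potential sampled on 60 sites is recovered at a
        held-out site within 10% of the field range."""
        pos = layout.positions
        dipole = np.array([0.3, 0.2, 0.93])
        dipole /= np.linalg.norm(dipole)
        field = pos @ dipole  # smooth order-1 spherical harmonic
        rng_range = field.max() - field.min()
        errs = []
        for i in range(0, len(pos), 7):
            others = [j for j in range(len(pos)) if j != i]
            A = spline_interpolation_matrix(pos[others], pos[[i]])
            errs.append(abs((A @ field[others])[0] - field[i]))
        assert max(errs) < 0.1 * rng_range

    def test_interpolate_channels_identity_and_targets(self, layout, clean_subject):
        _, rec, _ = clean_subject
        same = interpolate_channels(rec, [])
        assert np.array_equal(same.data, rec.data)
        out = interpolate_channels(rec, [4])
        assert np.array_equal(out.data[5], rec.data[5])  # good untouched
        assert not np.array_equal(out.data[4], rec.data[4])
        # interpolated channel should resemble a real field, not noise
        c = np.corrcoef(out.data[4], rec.data[4])[0, 1]
        assert c > 0.5

    def test_too_many_bad_refused(self, layout, clean_subject):
        _, rec, _ = clean_subject
        with pytest.raises(QualityError):
            interpolate_channels(rec, list(range(12)))


class TestBadChannels:
    def test_clean_recording_is_clean(self, clean_subject):
        _, rec, _ = clean_subject
        assert detect_bad_channels(rec) == []

    def test_flat_channel_flagged(self, clean_subject):
        _, rec, _ = clean_subject
        bad = rec.copy()
        bad.data[7, : int(6 * rec.sfreq)] = 3.14  # constant for 6 s
        assert 7 in detect_bad_channels(bad)

    def test_white_noise_channel_flagged(self, clean_subject):
        _, rec, _ = clean_subject
        bad = rec.copy()
        rng = np.random.default_rng(0)
        bad.data[11] = rng.normal(0, bad.data[11].std(), bad.n_samples)
        assert detect_bad_channels(bad) == [11]

    def test_mass_failure_raises_quality_error(self, clean_subject):
        _, rec, _ = clean_subject
        bad = rec.copy()
        rng = np.random.default_rng(1)
        for ch in range(12):  # > 15% of 60
            bad.data[ch] = rng.normal(0, 5.0, bad.n_samples)
        with pytest.raises(QualityError):
            detect_bad_channels(bad)

    def test_needs_enough_channels(self, layout):
        rec = _sine_rec(layout, [(10.0, 1.0)], n_ch=4)
        with pytest.raises(ConfigurationError):
            detect_bad_channels(rec)


class TestWindowRejection:
    def test_clean_keeps_everything(self, clean_subject):
        _, rec, _ = clean_subject
        _, keep = reject_contaminated_windows(rec)
        assert keep.all()

    def test_majority_burst_dropped_minority_kept(self, clean_subject):
        _, rec, _ = clean_subject
        sf = int(rec.sfreq)
        dirty = rec.copy()
        t = np.arange(sf) / sf
        burst = 500.0 * np.sin(2 * np.pi * 10 * t)
        dirty.data[:55, 10 * sf : 11 * sf] += burst  # 55/60 channels
        dirty.data[:10, 20 * sf : 21 * sf] += burst  # 10/60 channels
        _, keep = reject_contaminated_windows(dirty)
        assert not keep[10 * sf : 11 * sf].any()
        assert keep[20 * sf : 21 * sf].all()

    def test_everything_rejected_raises(self, layout):
        rng = np.random.default_rng(2)
        data = 1000.0 * rng.normal(size=(10, 2500))
        rec = simple_recording(data, layout)
        with pytest.raises(QualityError):
            reject_contaminated_windows(rec)


class TestReference:
    def test_zero_mean_and_idempotent(self, clean_subject):
        _, rec, _ = clean_subject
        out = average_reference(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9
        again = average_reference(out)
        assert np.allclose(again.data, out.data)

    def test_balanced_pair_unchanged(self, layout):
        rec = simple_recording(np.array([[5.0, 5.0], [-5.0, -5.0]]), layout)
        out = average_reference(rec)
        assert np.array_equal(out.data, rec.data)


class TestSegmentation:
    def test_epoch_geometry_and_counts(self, clean_subject):
        scn, rec, ann = clean_subject
        es = segment_epochs(rec, ann)
        assert es.count("BL2") == es.count("AO") == es.count("AE") == scn.n_trials
        for ep, cond in zip(es.epochs, es.conditions):
            assert ep.shape[1] == (500 if cond == "BL2" else 375)
        assert sum(s.shape[1] for s in es.bl1_segments) == int(30 * rec.sfreq)

    def test_event_epoch_precedes_button_press(self, layout):
        """An AE press annotated at t = 100 s yields the span [98.5, 100)."""
        rng = np.random.default_rng(3)
        rec = simple_recording(rng.normal(size=(8, 110 * 250)), layout)
        marker = np.arange(rec.n_samples, dtype=float)
        rec.data[0] = marker / 250.0  # channel encoding time in seconds
        ann = AnnotationSet(pd.DataFrame({
            "onset_s": [98.5], "duration_s": [1.5], "condition": ["AE"],
            "trial_index": [0], "valid": [1], "hand": ["R"],
        }))
        es = segment_epochs(rec, ann)
        assert es.epochs[0].shape[1] == 375
        assert es.epochs[0][0, 0] == pytest.approx(98.5)
        assert es.epochs[0][0, -1] == pytest.approx(100.0 - 1 / 250)

    def test_invalid_and_rejected_epochs_dropped(self, clean_subject):
        scn, rec, ann = clean_subject
        df = ann.df.copy()
        ao_rows = df[df["condition"] == "AO"].index[:3]
        df.loc[ao_rows, "valid"] = 0
        es = segment_epochs(rec, AnnotationSet(df))
        assert es.count("AO") == scn.n_trials - 3

        keep = np.ones(rec.n_samples, bool)
        ae0 = ann.of("AE").iloc[0]
        mid = int((ae0["onset_s"] + 0.5) * rec.sfreq)
        keep[mid : mid + 10] = False
        es2 = segment_epochs(rec, ann, keep_mask=keep)
        assert es2.count("AE") == scn.n_trials - 1


class TestEpochRejection:
    def test_spike_removed_clean_identity(self, clean_subject, layout):
        _, rec, ann = clean_subject
        es = segment_epochs(rec, ann)
        clean = reject_artifact_epochs(es)
        assert len(clean.epochs) == len(es.epochs)  # clean data: identity
        es.epochs[2][0, 5] = 250.0
        fewer = reject_artifact_epochs(es)
        assert len(fewer.epochs) == len(es.epochs) - 1

    def test_insufficient_condition_flagging(self, clean_subject):
        _, rec, ann = clean_subject
        es = segment_epochs(rec, ann)
        ae = es.indices("AE")
        keep = [i for i in range(len(es.epochs)) if i not in set(ae[4:])]
        reduced = es.select(keep)  # only 4 AE epochs survive
        assert insufficient_conditions(reduced) == ["AE"]
        assert insufficient_conditions(es) == []


def test_module_is_near_identity_on_bandlimited_clean_data(layout):
    """A continuous in-band signal passes filter + reference + segmentation
    nearly untouched (deviations only from filter passband ripple)."""
    sfreq = 250.0
    t = np.arange(int(60 * sfreq)) / sfreq
    rng = np.random.default_rng(21)
    gains = rng.uniform(1.0, 3.0, size=12)
    data = gains[:, None] * (5.0 * np.sin(2 * np.pi * 10 * t))[None, :]
    rec = simple_recording(data, layout, sfreq)
    ann = AnnotationSet(pd.DataFrame({
        "onset_s": [35.0, 38.0, 40.0],
        "duration_s": [2.0, 1.5, 1.5],
        "condition": ["BL2", "AO", "AE"],
        "trial_index": [0, 0, 0],
        "valid": [1, 1, 1],
        "hand": ["NA", "NA", "R"],
    }))
    ref = average_reference(rec)
    filtered = average_reference(bandpass_filter(rec))
    es_ref = segment_epochs(ref, ann)
    es_out = segment_epochs(filtered, ann)
    for a, b in zip(es_ref.epochs, es_out.epochs):
        assert np.abs(a - b).max() < 0.05 * np.abs(a).max()
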