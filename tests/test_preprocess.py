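"""Signal conditioning: filters, re-referencing, rejection, baselining,
normalization and sliding windows."""

import numpy as np
import pytest

from conftest import make_epochs
from odorbci.preprocess import (ArtifactParams, Window, baseline_subtract,
                                crop, filter_resample, hilbert_z_reject,
                                make_windows, percentile_normalize,
                                rereference_common_average)


class TestFilterResample:
    def test_notch_removes_line_noise(self):
        sfreq = 512.0
        t = np.arange(int(5 * sfreq)) / sfreq - 1.0
        sine = np.sin(2 * np.pi * 50.0 * t)
        es = make_epochs(n_trials=2, n_channels=2, n_samples=len(t),
                         sfreq=sfreq, t0=-1.0,
                         data=np.tile(sine, (2, 2, 1)))
        out = filter_resample(es, lowpass=None, notch=50.0, target_sfreq=sfreq)
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # avoid filter edges
        assert np.sqrt((out.data[..., mid] ** 2).mean()) < 0.05 * np.sqrt(
            (es.data[..., mid] ** 2).mean())

    def test_dc_passes_lowpass(self):
        es = make_epochs(n_trials=2, n_channels=2, n_samples=2560, sfreq=512.0,
                         data=np.full((2, 2, 2560), 3.25))
        out = filter_resample(es, lowpass=120.0, notch=None, target_sfreq=512.0)
        assert np.allclose(out.data, es.data, rtol=1e-6)

    def test_downsample_halves_samples(self):
        es = make_epochs(n_samples=2560, sfreq=512.0)
        out = filter_resample(es, lowpass=120.0, notch=None, target_sfreq=256.0)
        assert abs(out.data.shape[-1] - 1280) <= 1
        assert out.sfreq == 256.0
        assert np.array_equal(out.labels, es.labels)
        assert np.allclose(np.diff(out.times), 1 / 256.0)

    def test_nyquist_violation_errors(self):
        es = make_epochs(sfreq=256.0)
        with pytest.raises(ValueError, match="Nyquist"):
            filter_resample(es, lowpass=120.0, notch=None, target_sfreq=128.0)


class TestRereference:
    def test_channel_mean_zero(self, rng):
        es = make_epochs(seed=3)
        out = rereference_common_average(es)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10

    def test_common_offset_invariance(self):
        es = make_epochs(seed=4)
        shifted = es.copy_with(data=es.data + 42.0)
        a = rereference_common_average(es)
        b = rereference_common_average(shifted)
        assert np.allclose(a.data, b.data)

    def test_two_channel_closed_form(self):
        a = np.sin(np.linspace(0, 10, 256))
        b = np.cos(np.linspace(0, 10, 256))
        es = make_epochs(n_trials=2, n_channels=2, n_samples=256,
                         data=np.stack([np.stack([a, b])] * 2))
        out = rereference_common_average(es)
        assert np.allclose(out.data[0, 0], (a - b) / 2)
        assert np.allclose(out.data[0, 1], (b - a) / 2)

    def test_single_channel_errors(self):
        es = make_epochs(n_channels=1)
        with pytest.raises(ValueError):
            rereference_common_average(es)


class TestHilbertReject:
    def test_homogeneous_trials_mostly_kept(self):
        kept = []
        for seed in range(20):
            es = make_epochs(n_trials=80, n_channels=4, n_samples=512, seed=seed)
            kept.append(hilbert_z_reject(es).mean())
        assert np.mean(kept) >= 0.95

    def test_outlier_trial_rejected(self):
        # the z of one outlier among n trials is bounded by (n-1)/sqrt(n),
        # so clearing the 7-SD threshold needs a decently sized session
        es = make_epochs(n_trials=80, n_channels=3, seed=9)
        data = es.data.copy()
        data[7] *= 100.0
        es = es.copy_with(data=data)
        mask = hilbert_z_reject(es)
        assert not mask[7]
        assert mask.sum() >= 78

    def test_infinite_threshold_keeps_all(self):
        es = make_epochs(n_trials=10, seed=2)
        assert hilbert_z_reject(es, ArtifactParams(np.inf)).all()


class TestBaseline:
    def test_constant_becomes_zero(self):
        es = make_epochs(n_samples=1024, sfreq=512.0, t0=-1.0,
                         data=np.full((12, 3, 1024), 5.0))
        out = baseline_subtract(es, (-1.0, -0.6))
        assert np.allclose(out.data, 0.0)

    def test_baseline_window_mean_zero(self):
        es = make_epochs(n_samples=1024, sfreq=512.0, t0=-1.0, seed=6)
        out = baseline_subtract(es, (-1.0, -0.6))
        sel = (out.times >= -1.0) & (out.times < -0.6)
        assert np.abs(out.data[..., sel].mean(axis=-1)).max() < 1e-10

    def test_linear_ramp_subtracts_midpoint(self):
        sfreq = 1000.0
        times = -1.0 + np.arange(2000) / sfreq
        es = make_epochs(n_trials=2, n_channels=1, n_samples=2000, sfreq=sfreq,
                         t0=-1.0, data=np.tile(times, (2, 1, 1)))
        out = baseline_subtract(es, (-1.0, -0.6))
        # mean of t over [-1, -0.6) is -0.8: x(t) - (-0.8)
        assert out.data[0, 0, 0] == pytest.approx(times[0] + 0.8, abs=1e-3)

    def test_window_outside_epoch_errors(self):
        es = make_epochs(t0=-0.25)
        with pytest.raises(ValueError):
            baseline_subtract(es, (-2.0, -1.5))


class TestPercentileNormalize:
    def test_postcondition(self):
        es = make_epochs(seed=8)
        out = percentile_normalize(es)
        for i in range(out.n_trials):
            assert np.percentile(np.abs(out.data[i]), 95) == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self):
        es = make_epochs(seed=8)
        a = percentile_normalize(es)
        b = percentile_normalize(es.copy_with(data=es.data * 7.3))
        assert np.allclose(a.data, b.data)

    def test_zero_trial_errors_with_index(self):
        es = make_epochs(n_trials=5, seed=8)
        data = es.data.copy()
        data[3] = 0.0
        with pytest.raises(ValueError, match="3"):
            percentile_normalize(es.copy_with(data=data))


class TestWindows:
    def test_six_windows_at_printed_starts(self):
        wins = make_windows(0.0, 1.0, 0.25, 0.10)
        starts = [w.t_start for w in wins]
        assert starts == pytest.approx([0.0, 0.15, 0.30, 0.45, 0.60, 0.75])
        assert all(w.length == pytest.approx(0.25) for w in wins)

    def test_non_overlapping_count(self):
        assert len(make_windows(0.0, 1.0, 0.25, 0.0)) == 4

    def test_errors(self):
        with pytest.raises(ValueError):
            make_windows(0.0, 0.2, 0.25, 0.1)
        with pytest.raises(ValueError):
            make_windows(0.0, 1.0, 0.25, 0.25)

    def test_crop_half_open(self):
        es = make_epochs(n_samples=512, sfreq=256.0, t0=-1.0)
        out = crop(es, Window(-0.5, 0.0))
        assert out.data.shape[-1] == 128
        assert out.times[0] == pytest.approx(-0.5)
        assert out.times[-1] < 0.0


def test_reapplication_is_noop():
    """Re-referencing and baselining are idempotent within tolerance."""
    es = make_epochs(n_samples=1024, sfreq=512.0, t0=-1.0, seed=10)
    once = baseline_subtract(rereference_common_average(es))
    twice = baseline_subtract(rereference_common_average(once))
    assert np.allclose(once.data, twice.data, atol=1e-10)
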