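"""Generator: trial design, determinism, burst injection, sniff model."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from conftest import small_config
from odorbci.synth import (ConfigError, EffectSpec, SessionConfig, SniffParams,
                           generate_session, inject_burst, select_trials,
                           synth_sniff)


class TestSessionDesign:
    def test_default_design_counts(self, default_session):
        """The reference design: 140 trials, 20 clean air, 120 odor."""
        es = default_session["eeg"]
        assert es.n_trials == 140
        assert int((es.labels == 0).sum()) == 20
        assert int(es.labels.sum()) == 120
        assert sorted(np.unique(es.intensity.astype(str))) == ["air", "high", "low"]

    def test_modalities_share_labels_and_shapes(self, default_session):
        ref = default_session["eeg"]
        for name, es in default_session.items():
            assert np.array_equal(es.labels, ref.labels), name
            assert list(es.intensity) == list(ref.intensity), name
        assert default_session["eeg"].n_channels == 64
        assert default_session["scalp_ebg"].n_channels == 4
        assert default_session["source_ebg"].n_channels == 4
        assert default_session["sniff"].n_channels == 1
        assert default_session["sniff"].sfreq == 400.0

    def test_same_seed_bit_identical(self):
        cfg = small_config(seed=77)
        a = generate_session(cfg)
        b = generate_session(cfg)
        for name in a:
            assert np.array_equal(a[name].data, b[name].data), name

    def test_invalid_config_names_invariant(self):
        with pytest.raises(ConfigError, match="n_blocks"):
            SessionConfig(n_air=25, n_odor_high=60, n_odor_low=60).validate()
        with pytest.raises(ConfigError, match="epoch_span"):
            SessionConfig(epoch_span=(0.5, 4.0)).validate()
        with pytest.raises(ConfigError, match="amplitude"):
            SessionConfig(effect=EffectSpec(amplitude=-1.0)).validate()

    def test_null_amplitude_no_condition_difference(self):
        """With amplitude 0 odor and air trials are exchangeable: two-sample
        t on mean band power, p approximately uniform over seeds."""
        pvals = []
        for seed in range(12):
            cfg = small_config(seed=seed, amplitude=0.0)
            s = generate_session(cfg)
            es = s["scalp_ebg"]
            sos = sps.butter(4, (50, 95), "bandpass", fs=es.sfreq, output="sos")
            filt = sps.sosfiltfilt(sos, es.data, axis=-1)
            sel = (es.times >= 0.5) & (es.times < 1.0)
            power = (filt[..., sel] ** 2).mean(axis=(1, 2))
            pvals.append(stats.ttest_ind(power[es.labels == 1],
                                         power[es.labels == 0]).pvalue)
        # uniform p-values: KS test should not reject at a generous level
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert 0.02 < np.mean(pvals)


@pytest.fixture(scope="module")
def default_session():
    return generate_session(SessionConfig(seed=5))


class TestInjectBurst:
    times = np.arange(-256, 768) / 256.0
    sfreq = 256.0

    def test_zero_amplitude_identity(self, rng):
        trial = rng.standard_normal((2, len(self.times)))
        out = inject_burst(trial, (50, 95), (0.5, 1.0), 0.0, 0.05, rng,
                           sfreq=self.sfreq, times=self.times)
        assert np.array_equal(out, trial)

    def test_zero_jitter_support_within_window(self, rng):
        trial = np.zeros((1, len(self.times)))
        out = inject_burst(trial, (50, 95), (0.5, 1.0), 1.0, 0.0, rng,
                           sfreq=self.sfreq, times=self.times)
        changed = np.abs(out[0]) > 0
        assert changed.any()
        assert self.times[changed].min() >= 0.5 - 1e-9
        assert self.times[changed].max() <= 1.0 + 1e-9

    def test_rect_sinusoid_band_power_gain(self, rng):
        """A rectangular-envelope sinusoid of amplitude a adds a^2/2 of
        power inside the window (Welch periodogram, within 10%)."""
        a = 2.0
        trial = np.zeros((1, len(self.times)))
        out = inject_burst(trial, (40.0, 40.0), (0.0, 1.0), a, 0.0, rng,
                           sfreq=self.sfreq, times=self.times, envelope="rect")
        sel = (self.times >= 0.0) & (self.times < 1.0)
        f, pxx = sps.periodogram(out[0, sel], fs=self.sfreq)
        total = np.trapezoid(pxx, f)
        assert total == pytest.approx(a ** 2 / 2.0, rel=0.10)

    def test_band_out_of_range_errors(self, rng):
        trial = np.zeros((1, len(self.times)))
        with pytest.raises(ValueError, match="band"):
            inject_burst(trial, (50, 200), (0.5, 1.0), 1.0, 0.0, rng,
                         sfreq=self.sfreq, times=self.times)
        with pytest.raises(ValueError, match="window"):
            inject_burst(trial, (50, 95), (3.0, 5.0), 1.0, 0.0, rng,
                         sfreq=self.sfreq, times=self.times)


class TestSniff:
    def test_noise_free_dip_depth(self, rng):
        p = SniffParams(dip_depth=1.7, noise_sd=0.0)
        tr = synth_sniff(0, p, rng)
        assert tr.min() == pytest.approx(-1.7, abs=1e-9)
        times = -1.0 + np.arange(tr.shape[1]) / 400.0
        assert np.all(tr[0, times < 0] == 0.0)

    def test_modulation_zero_same_distribution(self):
        p = SniffParams(noise_sd=0.0)
        a = synth_sniff(1, p, np.random.default_rng(0), modulation=0.0)
        b = synth_sniff(0, p, np.random.default_rng(0), modulation=0.0)
        assert np.allclose(a, b)

    def test_fixed_seed_identical(self):
        p = SniffParams()
        a = synth_sniff(1, p, np.random.default_rng(42))
        b = synth_sniff(1, p, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_odor_stretches_recovery(self, rng):
        p = SniffParams(noise_sd=0.0)
        odor = synth_sniff(1, p, rng)
        air = synth_sniff(0, p, rng)
        # during recovery the odor trace stays deeper (slower return)
        times = -1.0 + np.arange(odor.shape[1]) / 400.0
        rec = (times > 1.0) & (times < 2.5)
        assert np.all(odor[0, rec] <= air[0, rec] + 1e-12)
        assert odor[0, rec].mean() < air[0, rec].mean()


class TestSelectTrials:
    def test_high_contrast_selection(self, default_session):
        """Keeping clean air + high-intensity odors leaves 60 odor and 20
        air trials of the 140."""
        sel = select_trials(default_session, {"high", "air"})
        es = sel["eeg"]
        assert es.n_trials == 80
        assert int(es.labels.sum()) == 60
        for other in sel.values():
            assert np.array_equal(other.labels, es.labels)

    def test_keep_all_and_order_preserved(self, default_session):
        sel = select_trials(default_session, {"high", "low", "air"})
        assert sel["eeg"].n_trials == 140
        assert np.array_equal(sel["eeg"].data, default_session["eeg"].data)

    def test_empty_or_bad_keep_errors(self, default_session):
        with pytest.raises(ValueError):
            select_trials(default_session, set())
        with pytest.raises(ValueError):
            select_trials(default_session, {"medium"})
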