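"""Synthetic multimodal olfactory sessions.

The real recordings behind this pipeline (64-channel EEG, 4-channel scalp
EBG, 4-ROI source-reconstructed olfactory-bulb/piriform activity, and an
intranasal thermistor "sniff" trace) are not publicly available, so every
downstream stage is exercised on surrogate sessions that reproduce the
experimental design — 4 blocks x 35 trials = 140 trials per participant,
120 odor exposures split over two intensities plus 20 clean-air controls,
epochs spanning -1..+4 s around sniff onset — and the signal structure the
analysis assumes: odor-evoked beta/gamma band-limited bursts riding on a
spatially mixed 1/f background, and an odor-modulated inhalation
temperature dip.

The generator states a world; its defaults are not fitted to any dataset.
Effect amplitude 0 yields an exact null (odor and air trials exchangeable),
which the evaluation-protocol tests rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ConfigError",
    "EffectSpec",
    "SniffParams",
    "SessionConfig",
    "EpochSet",
    "generate_session",
    "inject_burst",
    "synth_sniff",
    "select_trials",
]


class ConfigError(ValueError):
    """A session configuration violates one of its invariants."""


@dataclass(frozen=True)
class EffectSpec:
    """Injected odor response: band-limited bursts on top of the background.

    amplitude is a unitless SNR multiplier (peak burst amplitude relative to
    the per-channel background RMS); 0 disables the effect entirely.
    """

    gamma_band: tuple[float, float] = (50.0, 95.0)
    beta_band: tuple[float, float] = (10.0, 30.0)
    response_window: tuple[float, float] = (0.5, 1.0)
    amplitude: float = 1.0
    latency_jitter_sd: float = 0.05
    channel_weights: np.ndarray | None = None
    background_exponent: float = 1.0
    low_intensity_scale: float = 0.5

    def validate(self, sfreq: float) -> None:
        nyq = sfreq / 2.0
        for name, band in (("gamma_band", self.gamma_band), ("beta_band", self.beta_band)):
            lo, hi = band
            if not (0.0 < lo < hi < nyq):
                raise ConfigError(f"{name} {band} must lie within (0, {nyq}) Hz")
        if self.amplitude < 0:
            raise ConfigError("effect amplitude must be >= 0")
        if self.latency_jitter_sd < 0:
            raise ConfigError("latency_jitter_sd must be >= 0")


@dataclass(frozen=True)
class SniffParams:
    """Inhalation temperature dip: negative half-Gaussian onset at t=0, a
    slower half-Gaussian recovery, odor trials stretch the recovery."""

    dip_depth: float = 1.0
    dip_time: float = 0.6          # s after sniff onset at which the dip bottoms out
    onset_width: float = 0.35      # s, SD of the descending half-Gaussian
    recovery_width: float = 0.9    # s, SD of the recovering half-Gaussian (air)
    modulation: float = 0.4        # fractional recovery-time stretch on odor trials
    noise_sd: float = 0.05


@dataclass(frozen=True)
class SessionConfig:
    n_blocks: int = 4
    trials_per_block: int = 35
    n_air: int = 20
    n_odor_high: int = 60
    n_odor_low: int = 60
    sfreq_neural: float = 512.0
    sfreq_sniff: float = 400.0
    epoch_span: tuple[float, float] = (-1.0, 4.0)
    n_eeg_channels: int = 64
    n_ebg_channels: int = 4
    n_source_rois: int = 4
    effect: EffectSpec = field(default_factory=EffectSpec)
    sniff: SniffParams = field(default_factory=SniffParams)
    seed: int = 0
    participant_id: str = "sub-synthetic-00"

    def validate(self) -> None:
        total = self.n_blocks * self.trials_per_block
        if self.n_air + self.n_odor_high + self.n_odor_low != total:
            raise ConfigError(
                "n_air + n_odor_high + n_odor_low "
                f"({self.n_air}+{self.n_odor_high}+{self.n_odor_low}) must equal "
                f"n_blocks * trials_per_block ({total})"
            )
        if not (self.epoch_span[0] < 0.0 < self.epoch_span[1]):
            raise ConfigError("epoch_span must straddle sniff onset: start < 0 < end")
        for name in ("n_blocks", "trials_per_block", "n_air", "n_odor_high",
                     "n_odor_low", "n_eeg_channels", "n_ebg_channels", "n_source_rois"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.sfreq_neural <= 0 or self.sfreq_sniff <= 0:
            raise ConfigError("sampling frequencies must be positive")
        self.effect.validate(self.sfreq_neural)


MODALITIES = ("eeg", "scalp_ebg", "source_ebg", "sniff")


@dataclass
class EpochSet:
    """Labeled multichannel trial epochs for one participant and modality.

    data: (n_trials, n_channels, n_samples); labels 1 = odor, 0 = clean air;
    intensity per trial in {"high", "low", "air"}.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    labels: np.ndarray
    intensity: np.ndarray
    modality: str
    participant_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        n, _, t = self.data.shape
        if len(self.times) != t:
            raise ValueError("times length must match sample count")
        if len(self.labels) != n or len(self.intensity) != n:
            raise ValueError("labels/intensity must have one entry per trial")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        air = self.intensity == "air"
        if not np.array_equal(air, self.labels == 0):
            raise ValueError("intensity == 'air' must coincide with label == 0")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "EpochSet":
        base = dict(data=self.data, sfreq=self.sfreq, times=self.times,
                    labels=self.labels, intensity=self.intensity,
                    modality=self.modality, participant_id=self.participant_id)
        base.update(kw)
        return EpochSet(**base)

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return self.copy_with(data=self.data[mask], labels=self.labels[mask],
                              intensity=self.intensity[mask])


def _times(span: tuple[float, float], sfreq: float) -> np.ndarray:
    n = int(round((span[1] - span[0]) * sfreq))
    return span[0] + np.arange(n) / sfreq


def one_over_f_noise(shape: tuple[int, ...], exponent: float, sfreq: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum along the last axis,
    scaled to unit standard deviation."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    amp = np.ones_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),)))
    x = np.fft.irfft(spec * amp, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _smooth_mixing_matrix(n_ch: int, rng: np.random.Generator) -> np.ndarray:
    """Random spatial mixing: identity plus a channel-smoothed random matrix,
    so neighbouring channels share background activity (volume conduction
    surrogate)."""
    raw = rng.standard_normal((n_ch, n_ch))
    if n_ch > 2:
        k = np.array([0.25, 0.5, 0.25])
        raw = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 0, raw)
    mix = np.eye(n_ch) + 0.35 * raw / np.sqrt(n_ch)
    # renormalize rows so background variance stays ~1 per channel
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    return mix


def inject_burst(trial: np.ndarray, band: tuple[float, float],
                 window: tuple[float, float], amplitude: float,
                 jitter: float, rng: np.random.Generator, *,
                 sfreq: float, times: np.ndarray,
                 channel_weights: np.ndarray | None = None,
                 envelope: str = "hann") -> np.ndarray:
    """Add a band-limited oscillatory burst with a smooth envelope to a trial.

    The carrier frequency is drawn uniformly from ``band``, the envelope is
    centred on the window midpoint jittered by N(0, jitter^2), and its
    support is the window length. ``amplitude`` is the peak carrier
    amplitude (per unit channel weight). Outside the envelope support the
    trial is returned unchanged.
    """
    nyq = sfreq / 2.0
    if not (0.0 < band[0] <= band[1] < nyq):
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    if window[0] < times[0] or window[1] > times[-1] + 1.0 / sfreq:
        raise ValueError(f"window {window} outside epoch span ({times[0]}, {times[-1]})")
    if amplitude == 0:
        return trial
    n_ch, n_samp = trial.shape
    if channel_weights is None:
        channel_weights = np.ones(n_ch)
    f = rng.uniform(band[0], band[1])
    phase = rng.uniform(0, 2 * np.pi)
    center = 0.5 * (window[0] + window[1]) + rng.normal(0.0, jitter)
    half = 0.5 * (window[1] - window[0])
    rel = (times - center) / half  # -1..1 inside the (jittered) window
    if envelope == "hann":
        env = np.where(np.abs(rel) < 1.0, 0.5 * (1 + np.cos(np.pi * rel)), 0.0)
    elif envelope == "rect":
        env = np.where(np.abs(rel) < 1.0, 1.0, 0.0)
    else:
        raise ValueError(f"unknown envelope {envelope!r}")
    carrier = np.sin(2 * np.pi * f * times + phase)
    burst = amplitude * env * carrier
    return trial + np.outer(channel_weights, burst)


def synth_sniff(label: int, params: SniffParams, rng: np.random.Generator, *,
                sfreq: float = 400.0,
                epoch_span: tuple[float, float] = (-1.0, 4.0),
                modulation: float | None = None) -> np.ndarray:
    """One thermistor-style inhalation trace (temperature proxy, 1 channel).

    Baseline 0 before sniff onset; at t=0 the temperature starts dropping
    (inhaled air is colder than the nasal mucosa), bottoms out at
    ``dip_time`` with depth ``dip_depth``, then recovers. Odor trials
    (label 1) stretch the recovery width by (1 + modulation).
    """
    mod = params.modulation if modulation is None else modulation
    times = _times(epoch_span, sfreq)
    trace = np.zeros_like(times)
    t0 = params.dip_time
    pre = times < t0
    post = ~pre
    onset_shape = np.exp(-0.5 * ((times - t0) / params.onset_width) ** 2)
    rec_width = params.recovery_width * (1.0 + mod * (1 if label else 0))
    rec_shape = np.exp(-0.5 * ((times - t0) / rec_width) ** 2)
    trace[pre] = -params.dip_depth * onset_shape[pre]
    trace[post] = -params.dip_depth * rec_shape[post]
    trace[times < 0] = 0.0
    if params.noise_sd > 0:
        # slow sensor noise: low-passed white noise
        noise = rng.standard_normal(times.shape)
        b = sps.firwin(65, 5.0, fs=sfreq)
        noise = sps.filtfilt(b, [1.0], noise)
        noise *= params.noise_sd / max(noise.std(), 1e-12)
        trace = trace + noise
    return trace[np.newaxis, :]


def _trial_design(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-trial intensity sequence, shuffled within the whole session."""
    intensity = np.array(["air"] * cfg.n_air + ["high"] * cfg.n_odor_high
                         + ["low"] * cfg.n_odor_low, dtype=object)
    rng.shuffle(intensity)
    return intensity


def _neural_epochs(cfg: SessionConfig, intensity: np.ndarray, n_ch: int,
                   modality: str, rng: np.random.Generator) -> EpochSet:
    times = _times(cfg.epoch_span, cfg.sfreq_neural)
    n_trials = len(intensity)
    eff = cfg.effect
    data = one_over_f_noise((n_trials, n_ch, len(times)),
                            eff.background_exponent, cfg.sfreq_neural, rng)
    mix = _smooth_mixing_matrix(n_ch, rng)
    data = np.einsum("dc,ncs->nds", mix, data)
    if eff.channel_weights is not None:
        weights = np.asarray(eff.channel_weights, dtype=float)
        if len(weights) != n_ch:
            raise ConfigError("channel_weights length must match channel count")
    else:
        # smooth positive gain profile, fixed per session/modality
        w = rng.standard_normal(n_ch)
        if n_ch > 2:
            w = np.convolve(w, np.ones(3) / 3.0, mode="same")
        weights = 0.5 + np.abs(w)
        weights /= weights.max()
    labels = (intensity != "air").astype(int)
    for i in range(n_trials):
        if labels[i] == 0 or eff.amplitude == 0:
            continue
        scale = 1.0 if intensity[i] == "high" else eff.low_intensity_scale
        for band in (eff.beta_band, eff.gamma_band):
            data[i] = inject_burst(
                data[i], band, eff.response_window,
                eff.amplitude * scale, eff.latency_jitter_sd, rng,
                sfreq=cfg.sfreq_neural, times=times, channel_weights=weights)
    return EpochSet(data=data, sfreq=cfg.sfreq_neural, times=times,
                    labels=labels, intensity=intensity, modality=modality,
                    participant_id=cfg.participant_id)


def generate_session(cfg: SessionConfig) -> dict[str, EpochSet]:
    """Generate one participant's session across all four modalities.

    Modalities share the trial order, labels and intensities; each modality
    draws from its own RNG stream derived from ``cfg.seed`` so it is
    reproducible independently.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    keys = ("design",) + MODALITIES
    streams = dict(zip(keys, (np.random.default_rng(s) for s in ss.spawn(len(keys)))))
    intensity = _trial_design(cfg, streams["design"])
    labels = (intensity != "air").astype(int)

    session = {
        "eeg": _neural_epochs(cfg, intensity, cfg.n_eeg_channels, "eeg", streams["eeg"]),
        "scalp_ebg": _neural_epochs(cfg, intensity, cfg.n_ebg_channels,
                                    "scalp_ebg", streams["scalp_ebg"]),
        "source_ebg": _neural_epochs(cfg, intensity, cfg.n_source_rois,
                                     "source_ebg", streams["source_ebg"]),
    }
    sniff_rng = streams["sniff"]
    mod = cfg.sniff.modulation if cfg.effect.amplitude > 0 else 0.0
    traces = [synth_sniff(int(lbl), cfg.sniff, sniff_rng, sfreq=cfg.sfreq_sniff,
                          epoch_span=cfg.epoch_span, modulation=mod)
              for lbl in labels]
    session["sniff"] = EpochSet(
        data=np.stack(traces), sfreq=cfg.sfreq_sniff,
        times=_times(cfg.epoch_span, cfg.sfreq_sniff), labels=labels,
        intensity=intensity, modality="sniff", participant_id=cfg.participant_id)
    return session


def select_trials(session: dict[str, EpochSet],
                  keep: set[str]) -> dict[str, EpochSet]:
    """Filter trials by intensity condition, consistently across modalities.

    The default analysis keeps {"high", "air"}: clean air versus
    high-intensity odor, the high-contrast subset."""
    allowed = {"high", "low", "air"}
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    if not keep <= allowed:
        raise ValueError(f"keep must be a subset of {allowed}, got {keep}")
    first = next(iter(session.values()))
    mask = np.isin(first.intensity.astype(str), sorted(keep))
    return {name: es.subset(mask) for name, es in session.items()}
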