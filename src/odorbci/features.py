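"""Hand-crafted features for the linear decoder.

Morlet time-frequency power (3-cycle complex wavelets over 5-100 Hz),
log10-ratio baseline correction against the -1.0..-0.6 s pre-sniff window,
equal-width frequency binning over the 10-70 Hz analysis band, per-feature
standardization fitted on training folds only, and PCA reduction for the
sniff trace. The TFR is computed on the full epoch and cropped afterwards
so the analysis window is free of wavelet edge effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA

from .preprocess import Window
from .synth import EpochSet

__all__ = [
    "TFRParams",
    "TFR",
    "morlet_tfr",
    "baseline_log_ratio",
    "bin_freqs",
    "standardize",
    "pca_reduce",
    "linear_feature_matrix",
    "sniff_feature_matrix",
]


@dataclass(frozen=True)
class TFRParams:
    freqs: np.ndarray = field(default_factory=lambda: np.arange(5.0, 101.0, 1.0))
    n_cycles: float = 3.0
    analysis_band: tuple[float, float] = (10.0, 70.0)
    n_freq_bins: int = 5
    baseline_window: tuple[float, float] = (-1.0, -0.6)

    def validate(self, sfreq: float) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or len(f) < 1 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be a strictly ascending 1-D grid")
        if f[0] <= 0 or f[-1] >= sfreq / 2.0:
            raise ValueError(f"freqs must lie within (0, {sfreq / 2.0}) Hz")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        lo, hi = self.analysis_band
        if not (f[0] <= lo < hi <= f[-1]):
            raise ValueError("analysis_band must lie within the frequency grid")


@dataclass
class TFR:
    """Per-trial time-frequency power: (trials, channels, freqs, times).

    Units are linear power until baseline correction, log10-ratio after."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    baseline_corrected: bool = False
    labels: np.ndarray | None = None

    def crop(self, t_start: float, t_end: float) -> "TFR":
        mask = (self.times >= t_start - 1e-9) & (self.times < t_end - 1e-9)
        if not mask.any():
            raise ValueError(f"crop window ({t_start}, {t_end}) contains no samples")
        return TFR(self.power[..., mask], self.freqs, self.times[mask],
                   self.sfreq, self.baseline_corrected, self.labels)

    def decimate(self, target_rate: float) -> "TFR":
        """Keep every k-th time sample so the effective rate is ~target_rate.
        Power is smooth in time at 3 cycles, so plain decimation suffices."""
        k = max(1, int(round(self.sfreq / target_rate)))
        return TFR(self.power[..., ::k], self.freqs, self.times[::k],
                   self.sfreq / k, self.baseline_corrected, self.labels)


def _morlet_wavelet(f: float, n_cycles: float, sfreq: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(5.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    # scale so a unit-amplitude sinusoid at f has |conv| ~ 1 (power ~ 1)
    return w / np.sum(np.abs(w))


def morlet_tfr(epochs: EpochSet, params: TFRParams = TFRParams()) -> TFR:
    """Complex-Morlet time-frequency power for every trial and channel.

    Computed over the full epoch; crop afterwards to keep the analysis
    window clear of edge effects. Power scales quadratically with signal
    amplitude."""
    params.validate(epochs.sfreq)
    freqs = np.asarray(params.freqs, dtype=float)
    n_samp = epochs.data.shape[-1]
    lowest = freqs[0]
    half_width = 5.0 * params.n_cycles / (2.0 * np.pi * lowest)
    span = n_samp / epochs.sfreq
    if 2 * half_width >= span:
        raise ValueError(
            f"epoch span {span:.3f}s too short for {lowest} Hz at "
            f"{params.n_cycles} cycles; need > {2 * half_width:.3f}s")
    n_trials, n_ch, _ = epochs.data.shape
    flat = epochs.data.reshape(n_trials * n_ch, n_samp)
    power = np.empty((n_trials, n_ch, len(freqs), n_samp))
    for fi, f in enumerate(freqs):
        w = _morlet_wavelet(f, params.n_cycles, epochs.sfreq)
        conv = sps.fftconvolve(flat, w[np.newaxis, :], mode="same", axes=-1)
        power[:, :, fi, :] = (np.abs(conv) ** 2).reshape(n_trials, n_ch, n_samp)
    return TFR(power=power, freqs=freqs, times=epochs.times.copy(),
               sfreq=epochs.sfreq, labels=epochs.labels.copy())


def baseline_log_ratio(tfr: TFR, window: tuple[float, float] = (-1.0, -0.6),
                       eps: float = 1e-12) -> TFR:
    """log10(power / mean baseline power), per trial, channel and frequency."""
    if tfr.baseline_corrected:
        raise ValueError("TFR is already baseline-corrected")
    mask = (tfr.times >= window[0]) & (tfr.times < window[1])
    if not mask.any():
        raise ValueError(f"baseline window {window} outside TFR times")
    base = tfr.power[..., mask].mean(axis=-1, keepdims=True)
    base = np.maximum(base, eps)
    out = np.log10(np.maximum(tfr.power, eps) / base)
    return TFR(out, tfr.freqs, tfr.times, tfr.sfreq,
               baseline_corrected=True, labels=tfr.labels)


def bin_freqs(tfr: TFR, band: tuple[float, float] | None = None,
              n_bins: int = 5) -> np.ndarray:
    """Average power within equal-width frequency bins over ``band``.

    Returns (trials, channels, n_bins, times). With the default 10-70 Hz
    band and 5 bins the edges are 10, 22, 34, 46, 58, 70 Hz."""
    if band is None:
        band = (float(tfr.freqs[0]), float(tfr.freqs[-1]))
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if band[0] < tfr.freqs[0] - 1e-9 or band[1] > tfr.freqs[-1] + 1e-9:
        raise ValueError(f"band {band} outside TFR frequency grid")
    edges = np.linspace(band[0], band[1], n_bins + 1)
    out = np.empty(tfr.power.shape[:2] + (n_bins,) + tfr.power.shape[3:])
    for b in range(n_bins):
        hi_incl = b == n_bins - 1
        sel = (tfr.freqs >= edges[b] - 1e-9) & (
            (tfr.freqs <= edges[b + 1] + 1e-9) if hi_incl
            else (tfr.freqs < edges[b + 1] - 1e-9))
        if not sel.any():
            raise ValueError(f"frequency bin [{edges[b]}, {edges[b + 1]}] "
                             "contains no grid frequency")
        out[:, :, b] = tfr.power[:, :, sel].mean(axis=2)
    return out


def standardize(train: np.ndarray, apply_to: np.ndarray | None = None,
                eps: float = 1e-12):
    """Per-feature z-scoring with statistics estimated on the training set.

    Returns (train_z, apply_z, (mean, sd)). Zero-variance features are
    mapped to 0 with a warning rather than dividing by zero."""
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need >= 2 training trials to standardize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    zero = sd < eps
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s); output set to 0",
                      RuntimeWarning, stacklevel=2)
        sd = np.where(zero, 1.0, sd)
    train_z = (train - mean) / sd
    apply_z = None if apply_to is None else (np.asarray(apply_to, float) - mean) / sd
    return train_z, apply_z, (mean, sd)


def pca_reduce(train: np.ndarray, apply_to: np.ndarray | None = None,
               var_kept: float = 0.95):
    """PCA fitted on the training set; keeps the smallest number of
    components whose cumulative explained variance reaches ``var_kept``."""
    if not (0 < var_kept <= 1):
        raise ValueError("var_kept must lie in (0, 1]")
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need >= 2 training trials for PCA")
    full = PCA(n_components=None, svd_solver="full").fit(train)
    if var_kept == 1.0:
        k = full.n_components_
    else:
        cum = np.cumsum(full.explained_variance_ratio_)
        k = int(np.searchsorted(cum, var_kept - 1e-12) + 1)
    pca = PCA(n_components=k, svd_solver="full").fit(train)
    train_r = pca.transform(train)
    apply_r = None if apply_to is None else pca.transform(np.asarray(apply_to, float))
    return train_r, apply_r, pca


def linear_feature_matrix(epochs: EpochSet, params: TFRParams = TFRParams(),
                          window: tuple[float, float] = (0.0, 1.0),
                          decim_rate: float = 50.0) -> np.ndarray:
    """TFR features for the linear decoder, flattened per trial.

    Full-epoch Morlet power -> log10-ratio baseline -> crop to the analysis
    window -> 5 equal frequency bins over 10-70 Hz -> decimation of the
    time axis to ~50 samples/s -> (trials, channels*bins*times)."""
    tfr = morlet_tfr(epochs, params)
    tfr = baseline_log_ratio(tfr, params.baseline_window)
    tfr = tfr.crop(*window).decimate(decim_rate)
    binned = bin_freqs(tfr, params.analysis_band, params.n_freq_bins)
    return binned.reshape(binned.shape[0], -1)


def sniff_feature_matrix(epochs: EpochSet,
                         window: tuple[float, float] = (0.0, 1.0),
                         lowpass: float = 50.0,
                         target_sfreq: float = 200.0) -> np.ndarray:
    """Temporal-domain sniff features: 50 Hz low-pass, 200 Hz resampling,
    crop to the analysis window, flatten. PCA happens inside the decoding
    pipeline so it is fitted on training folds only."""
    from .preprocess import crop, filter_resample

    out = filter_resample(epochs, lowpass=lowpass, notch=None,
                          target_sfreq=target_sfreq)
    out = crop(out, Window(*window))
    return out.data.reshape(out.n_trials, -1)
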