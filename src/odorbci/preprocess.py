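"""Signal conditioning for epoched bio-signals.

Filtering and resampling, common-average re-referencing, Hilbert-envelope
artifact rejection, pre-stimulus baseline subtraction, per-trial amplitude
normalization, and the sliding analysis windows. All operations preserve
trial count (rejection only returns a mask), label alignment and metadata.

Filters are zero-phase (forward-backward) so time-locked windows keep their
latencies: the low-pass is a windowed-sinc FIR with a transition band of
25% of the cutoff; the power-line notch is a narrow zero-phase IIR notch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import EpochSet

__all__ = [
    "ArtifactParams",
    "Window",
    "filter_resample",
    "rereference_common_average",
    "hilbert_z_reject",
    "baseline_subtract",
    "percentile_normalize",
    "make_windows",
    "crop",
    "resample",
]


@dataclass(frozen=True)
class ArtifactParams:
    """Muscle-artifact rejection threshold on the z-scored Hilbert envelope."""

    z_threshold: float = 7.0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")


@dataclass(frozen=True, order=True)
class Window:
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


def _fir_lowpass(cutoff: float, sfreq: float) -> np.ndarray:
    """Windowed-sinc low-pass, transition bandwidth 25% of the cutoff."""
    trans = 0.25 * cutoff
    numtaps = int(np.ceil(3.3 * sfreq / trans))  # Hamming-window rule of thumb
    numtaps += 1 - numtaps % 2  # odd for a type-I linear-phase filter
    return sps.firwin(numtaps, cutoff, fs=sfreq, window="hamming")


def filter_resample(epochs: EpochSet, lowpass: float | None,
                    notch: float | None, target_sfreq: float) -> EpochSet:
    """Low-pass (zero-phase FIR), optional notch, then polyphase resampling."""
    sfreq = epochs.sfreq
    if target_sfreq > sfreq:
        raise ValueError(f"cannot upsample: target {target_sfreq} > original {sfreq}")
    if lowpass is not None and not (lowpass < target_sfreq / 2.0 <= sfreq / 2.0):
        raise ValueError(
            f"Nyquist violation: need lowpass ({lowpass}) < target_sfreq/2 "
            f"({target_sfreq / 2.0}) <= original sfreq/2 ({sfreq / 2.0})")
    data = epochs.data
    if notch is not None:
        if notch >= sfreq / 2.0:
            raise ValueError(f"notch {notch} Hz at or above Nyquist {sfreq / 2.0}")
        b, a = sps.iirnotch(notch, Q=30.0, fs=sfreq)
        data = sps.filtfilt(b, a, data, axis=-1)
    if lowpass is not None:
        taps = _fir_lowpass(lowpass, sfreq)
        data = sps.filtfilt(taps, [1.0], data, axis=-1)
    if target_sfreq != sfreq:
        from fractions import Fraction

        frac = Fraction(target_sfreq / sfreq).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    times = epochs.times[0] + np.arange(data.shape[-1]) / target_sfreq
    return epochs.copy_with(data=data, sfreq=target_sfreq, times=times)


def resample(epochs: EpochSet, target_sfreq: float) -> EpochSet:
    """Polyphase resampling to an arbitrary rate (up or down), without
    additional filtering — used to harmonize modality rates (e.g. the
    200 Hz sniff trace to the 256 Hz neural grid) before early fusion."""
    if target_sfreq == epochs.sfreq:
        return epochs
    from fractions import Fraction

    frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
    data = sps.resample_poly(epochs.data, frac.numerator, frac.denominator,
                             axis=-1)
    times = epochs.times[0] + np.arange(data.shape[-1]) / target_sfreq
    return epochs.copy_with(data=data, sfreq=target_sfreq, times=times)


def rereference_common_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over channels from every channel."""
    if epochs.n_channels < 2:
        raise ValueError("common-average reference undefined for a single channel")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def hilbert_z_reject(epochs: EpochSet,
                     params: ArtifactParams = ArtifactParams()) -> np.ndarray:
    """Keep-mask over trials from the z-scored Hilbert amplitude.

    Per trial and channel the maximum of the analytic-signal envelope is
    taken; maxima are z-scored across trials within each channel; a trial
    is rejected when any channel's z exceeds the threshold (default 7).
    """
    if epochs.n_trials < 3:
        raise ValueError("need at least 3 trials to z-score envelope maxima")
    env = np.abs(sps.hilbert(epochs.data, axis=-1))
    peak = env.max(axis=-1)  # (trials, channels)
    mu = peak.mean(axis=0, keepdims=True)
    sd = peak.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (peak - mu) / sd
    return z.max(axis=1) <= params.z_threshold


def baseline_subtract(epochs: EpochSet,
                      window: tuple[float, float] = (-1.0, -0.6)) -> EpochSet:
    """Remove the mean activity over a pre-stimulus window per trial/channel."""
    t = epochs.times
    mask = (t >= window[0]) & (t < window[1])
    if window[0] < t[0] - 0.5 / epochs.sfreq or window[1] > t[-1] + 1.5 / epochs.sfreq \
            or not mask.any():
        raise ValueError(f"baseline window {window} outside epoch span ({t[0]}, {t[-1]})")
    base = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def percentile_normalize(epochs: EpochSet, q: float = 95.0) -> EpochSet:
    """Divide each trial by the q-th percentile of its absolute amplitude,
    pooled over channels and samples."""
    scale = np.percentile(np.abs(epochs.data), q, axis=(1, 2))
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        raise ValueError(f"trial(s) {bad.tolist()} have zero amplitude; "
                         "cannot percentile-normalize")
    return epochs.copy_with(data=epochs.data / scale[:, None, None])


def make_windows(t_start: float, t_end: float, length: float,
                 overlap: float) -> list[Window]:
    """Sliding windows of ``length`` stepping by ``length - overlap``.

    Windows start at t_start + k*(length - overlap) for k = 0, 1, ... while
    they fit fully inside [t_start, t_end]. The default analysis uses six
    250-ms windows with 100-ms overlap over the first post-onset second.
    """
    span = t_end - t_start
    if length > span:
        raise ValueError(f"window length {length} exceeds span {span}")
    if not (0 <= overlap < length):
        raise ValueError(f"need 0 <= overlap ({overlap}) < length ({length})")
    step = length - overlap
    out: list[Window] = []
    k = 0
    tol = 1e-9
    while t_start + k * step + length <= t_end + tol:
        s = t_start + k * step
        out.append(Window(round(s, 9), round(s + length, 9)))
        k += 1
    return out


def crop(epochs: EpochSet, window: Window | tuple[float, float]) -> EpochSet:
    """Half-open crop [t_start, t_end) in sample indexing."""
    if isinstance(window, tuple):
        window = Window(*window)
    t = epochs.times
    mask = (t >= window.t_start - 1e-9) & (t < window.t_end - 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return epochs.copy_with(data=epochs.data[..., mask], times=t[mask])
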