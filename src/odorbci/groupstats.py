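"""Group-level spectrogram contrast and cluster-based permutation testing.

Per participant the average odor-trial spectrogram is contrasted with the
average clean-air spectrogram; across participants a dependent-samples t
map is formed per time-frequency bin and evaluated with a nonparametric
cluster-based permutation test: the t map is thresholded at the two-sided
parametric t criterion, suprathreshold bins are grouped by 4-neighbor
adjacency separately by sign, each cluster's mass is the sum of its t
values, and the Monte-Carlo null is built by randomly sign-flipping whole
participants' difference maps and recording the maximum absolute cluster
mass per permutation. Cluster p-values are (1 + #{null >= observed}) /
(n_permutations + 1), so they can never fall below 1/(n_permutations + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .features import TFR

__all__ = [
    "ClusterParams",
    "Cluster",
    "ClusterResult",
    "tf_contrast",
    "dependent_t_map",
    "cluster_perm_test",
    "split_performers",
]


@dataclass(frozen=True)
class ClusterParams:
    n_permutations: int = 100
    freq_range: tuple[float, float] = (4.0, 100.0)
    time_range: tuple[float, float] = (-0.2, 1.0)
    cluster_alpha: float = 0.05   # cluster-forming threshold (two-sided)
    alpha: float = 0.05           # significance level for reporting
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for a in (self.cluster_alpha, self.alpha):
            if not (0 < a < 1):
                raise ValueError("alpha levels must lie in (0, 1)")


@dataclass
class Cluster:
    mask: np.ndarray        # boolean (freqs, times)
    sign: int               # +1 or -1
    mass: float             # sum of t values over the cluster
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    t_threshold: float
    freqs: np.ndarray
    times: np.ndarray
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]


def tf_contrast(tfr_odor: TFR, tfr_air: TFR) -> np.ndarray:
    """One participant's odor-minus-air average spectrogram.

    Trial-averaged within condition, then averaged over channels, yielding
    a (freqs, times) difference map."""
    if tfr_odor.freqs.shape != tfr_air.freqs.shape \
            or tfr_odor.times.shape != tfr_air.times.shape \
            or not np.allclose(tfr_odor.freqs, tfr_air.freqs) \
            or not np.allclose(tfr_odor.times, tfr_air.times):
        raise ValueError("time-frequency grids do not match between conditions")
    mean_odor = tfr_odor.power.mean(axis=(0, 1))
    mean_air = tfr_air.power.mean(axis=(0, 1))
    return mean_odor - mean_air


def dependent_t_map(diffs: np.ndarray) -> np.ndarray:
    """Per-bin one-sample t of participant difference maps against 0.

    diffs: (participants, freqs, times); df = N - 1. Zero-variance bins are
    mapped to t = 0 with a warning rather than +/-inf."""
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants for a dependent-samples t")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance bin(s): t set to 0",
                      RuntimeWarning, stacklevel=2)
        sd = np.where(zero, 1.0, sd)
    t = mean / (sd / np.sqrt(n))
    return np.where(zero, 0.0, t)


_ADJACENCY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity


def _clusters_and_masses(t_map: np.ndarray, thresh: float):
    """Suprathreshold clusters by sign; returns list of (mask, sign, mass)."""
    out = []
    for sign in (1, -1):
        supra = (sign * t_map) > thresh
        lab, n_lab = ndimage.label(supra, structure=_ADJACENCY)
        for i in range(1, n_lab + 1):
            mask = lab == i
            out.append((mask, sign, float(t_map[mask].sum())))
    return out


def cluster_perm_test(diffs: np.ndarray, params: ClusterParams = ClusterParams(),
                      rng: np.random.Generator | None = None,
                      freqs: np.ndarray | None = None,
                      times: np.ndarray | None = None) -> ClusterResult:
    """Cluster-based permutation test on participant difference maps.

    diffs: (participants, freqs, times), already restricted to the analysis
    ranges (when ``freqs``/``times`` are given, the restriction to
    ``params.freq_range`` / ``params.time_range`` is applied here).
    """
    params.validate()
    diffs = np.asarray(diffs, dtype=float)
    if not np.isfinite(diffs).all():
        raise ValueError("difference maps contain NaN/Inf")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if freqs is not None:
        fsel = (freqs >= params.freq_range[0]) & (freqs <= params.freq_range[1])
        diffs = diffs[:, fsel, :]
        freqs = freqs[fsel]
    if times is not None:
        tsel = (times >= params.time_range[0]) & (times <= params.time_range[1])
        diffs = diffs[:, :, tsel]
        times = times[tsel]
    n = diffs.shape[0]
    df = n - 1
    t_thresh = float(stats.t.ppf(1.0 - params.cluster_alpha / 2.0, df))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_obs = dependent_t_map(diffs)
    observed = _clusters_and_masses(t_obs, t_thresh)

    null_max = np.zeros(params.n_permutations)
    for p_i in range(params.n_permutations):
        signs = rng.choice((-1.0, 1.0), size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_perm = dependent_t_map(diffs * signs[:, None, None])
        masses = [abs(m) for _, _, m in _clusters_and_masses(t_perm, t_thresh)]
        null_max[p_i] = max(masses) if masses else 0.0

    clusters = []
    for mask, sign, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (params.n_permutations + 1.0)
        clusters.append(Cluster(mask=mask, sign=sign, mass=mass, p=float(p)))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(clusters=clusters, t_map=t_obs, t_threshold=t_thresh,
                         freqs=freqs if freqs is not None else np.empty(0),
                         times=times if times is not None else np.empty(0),
                         null_max_mass=null_max)


def split_performers(per_participant_auc: dict[str, float],
                     k: int = 15) -> tuple[list[str], list[str]]:
    """The k best- and k worst-performing participants by decoding AUC.

    Ties across the cut are broken deterministically by participant
    identifier. The two sets are disjoint (requires >= 2k participants)."""
    if len(per_participant_auc) < 2 * k:
        raise ValueError(
            f"need >= {2 * k} participants, got {len(per_participant_auc)}")
    by_desc = sorted(per_participant_auc, key=lambda p: (-per_participant_auc[p], p))
    top = sorted(by_desc[:k])
    bottom = sorted(by_desc[len(by_desc) - k:])
    return top, bottom
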