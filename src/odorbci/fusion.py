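"""Multimodal combination schemes.

Three ways to combine two modalities: (1) late fusion of linear-decoder
probabilities with validation-performance weights, (2) early fusion by
channel concatenation of sampling-rate-harmonized epochs, and (3) a hybrid
network with two convolutional encoders whose embeddings are concatenated
and mapped to a probability by one linear sigmoid unit (trained jointly,
end to end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import ensemble_weights
from .net import NetSpec, ResNet1D, _Dense, _sigmoid
from .synth import EpochSet

__all__ = [
    "FusionWeights",
    "late_fuse_probabilities",
    "early_fuse",
    "HybridNet",
    "build_hybrid_net",
]


@dataclass(frozen=True)
class FusionWeights:
    """Normalized non-negative weights for two models, derived from their
    validation AUCs: w proportional to max(AUC - 0.5, eps)."""

    w_a: float
    w_b: float

    def __post_init__(self) -> None:
        if self.w_a < 0 or self.w_b < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_a + self.w_b - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_validation_aucs(cls, auc_a: float, auc_b: float,
                             eps: float = 1e-6) -> "FusionWeights":
        w = ensemble_weights(np.array([auc_a, auc_b]), eps=eps)
        return cls(float(w[0]), float(w[1]))


def late_fuse_probabilities(p_a: np.ndarray, p_b: np.ndarray,
                            w: FusionWeights) -> np.ndarray:
    """Validation-weighted average of two aligned probability vectors."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError(
            f"trial misalignment: {p_a.shape} vs {p_b.shape}")
    return w.w_a * p_a + w.w_b * p_b


def early_fuse(epochs_a: EpochSet, epochs_b: EpochSet) -> EpochSet:
    """Stack two modalities as extra channels of one epoch set.

    Requires identical trials/labels and a common sampling rate (resample
    both to 256 Hz first, matching the pipeline's harmonized rate)."""
    if not np.array_equal(epochs_a.labels, epochs_b.labels):
        raise ValueError("label vectors differ between modalities")
    if not np.array_equal(epochs_a.intensity.astype(str),
                          epochs_b.intensity.astype(str)):
        raise ValueError("intensity vectors differ between modalities")
    if epochs_a.sfreq != epochs_b.sfreq:
        raise ValueError(
            f"sampling rates differ ({epochs_a.sfreq} vs {epochs_b.sfreq} Hz); "
            "resample both modalities to a common rate (e.g. 256 Hz) first")
    n = min(epochs_a.data.shape[-1], epochs_b.data.shape[-1])
    data = np.concatenate([epochs_a.data[..., :n], epochs_b.data[..., :n]], axis=1)
    return epochs_a.copy_with(
        data=data, times=epochs_a.times[:n],
        modality=f"{epochs_a.modality}+{epochs_b.modality}")


class HybridNet:
    """Dual-encoder late-fusion network.

    Two ResNet-1D trunks (classification heads removed) embed their
    modalities; the concatenated embedding feeds a single linear layer with
    a sigmoid. Input to forward/backward is a tuple (x_a, x_b)."""

    def __init__(self, spec_a: NetSpec, spec_b: NetSpec):
        self.enc_a = ResNet1D(spec_a)
        self.enc_b = ResNet1D(spec_b)
        self.embedding_dim = spec_a.embedding_dim + spec_b.embedding_dim
        rng = np.random.default_rng(spec_a.seed + 7919 * (spec_b.seed + 1))
        self.head = _Dense(self.embedding_dim, 1, rng)
        self._split = spec_a.embedding_dim

    def params(self):
        return self.enc_a.params()[:-2] + self.enc_b.params()[:-2] \
            + self.head.params()

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self):
        import copy

        return copy.deepcopy(
            [p.value for p in self.params()]
            + [[bn.running_mean, bn.running_var]
               for bn in self.enc_a._batchnorms() + self.enc_b._batchnorms()])

    def load_state_dict(self, state):
        params = self.params()
        for p, v in zip(params, state[:len(params)]):
            p.value[...] = v
        bns = self.enc_a._batchnorms() + self.enc_b._batchnorms()
        for bn, (m, v) in zip(bns, state[len(params):]):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def forward(self, x: tuple[np.ndarray, np.ndarray],
                train: bool = False) -> np.ndarray:
        xa, xb = x
        emb = np.concatenate([self.enc_a.embed(xa, train),
                              self.enc_b.embed(xb, train)], axis=1)
        z = self.head.forward(emb, train)[:, 0]
        return np.clip(_sigmoid(z), 1e-12, 1 - 1e-12)

    def backward_from_probs(self, probs: np.ndarray, y: np.ndarray) -> None:
        n = len(y)
        dz = ((probs - y) / n)[:, None]
        demb = self.head.backward(dz)
        for enc, d in ((self.enc_a, demb[:, :self._split]),
                       (self.enc_b, demb[:, self._split:])):
            n_, c, L = enc._emb_cache
            dh = np.repeat(d[:, :, None], L, axis=2) / L
            for blk in reversed(enc.blocks):
                dh = blk.backward(dh)
            dh = enc.stem_relu.backward(dh)
            dh = enc.stem_bn.backward(dh)
            enc.stem.backward(dh)


def build_hybrid_net(spec_a: NetSpec, spec_b: NetSpec) -> HybridNet:
    return HybridNet(spec_a, spec_b)
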