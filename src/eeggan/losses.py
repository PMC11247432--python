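"""GAN and classifier objectives.

The GAN is trained with least-squares targets: the discriminator pushes its
score to 1 on real and 0 on generated trials; the generator pushes the score
on its samples toward 1 and additionally matches intermediate discriminator
features of real and generated batches (feature matching), weighted by
``lam``.  The classifier objective averages per-crop class probabilities over
each trial's sliding windows before taking the negative log-likelihood
(optionally the focal variant) of the true class.

All functions accept numpy arrays or autodiff Tensors and return a Tensor;
call ``.item()`` for the scalar value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

logger = logging.getLogger("eeggan")

__all__ = [
    "GanLossTerms",
    "basic_generator_loss",
    "feature_matching_loss",
    "generator_loss",
    "discriminator_loss",
    "cropped_loss",
    "cropped_loss_batch",
]

DEFAULT_LAMBDA = 0.5  # weight of the feature-matching term


@dataclass
class GanLossTerms:
    """Scalar loss values of one training step, for logging."""

    L_M: float
    L_F: float
    L_G: float
    L_D: float


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def basic_generator_loss(d_scores_on_fake) -> Tensor:
    """Mean squared distance of discriminator scores on fakes from the real target 1."""
    s = _lift(d_scores_on_fake)
    if s.data.size == 0:
        raise ValueError("empty batch")
    return ((s.reshape(-1) - 1.0) ** 2).mean()

def feature_matching_loss(real_features, gen_features) -> Tensor:
    """(1/n) sum_i sum_j (R_ij - G_ij)^2 over per-sample feature vectors."""
    r, g = _lift(real_features), _lift(gen_features)
    if r.shape != g.shape:
        raise ValueError(f"feature shapes differ: {r.shape} vs {g.shape}")
    return ((r - g) ** 2).sum(axis=tuple(range(1, r.ndim))).mean()


def generator_loss(l_m, l_f, lam: float = DEFAULT_LAMBDA) -> Tensor:
    """Total generator objective L_G = L_M + lam * L_F."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return _lift(l_m) + lam * _lift(l_f)


def discriminator_loss(d_real, d_fake) -> Tensor:
    """(sum (D(real)-1)^2 + sum D(fake)^2) / (2n)."""
    r, f = _lift(d_real), _lift(d_fake)
    n = r.data.size
    if n == 0 or f.data.size != n:
        raise ValueError(f"batches must be equal-length and non-empty: {n} vs {f.data.size}")
    return (((r.reshape(-1) - 1.0) ** 2).sum() + (f.reshape(-1) ** 2).sum()) * (1.0 / (2 * n))


def _renormalize_rows(p: Tensor, what: str) -> Tensor:
    sums = p.data.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        logger.warning("%s rows do not sum to 1 (max dev %.3g); renormalizing",
                       what, float(np.abs(sums - 1).max()))
    return p / p.sum(axis=-1, keepdims=True)


def cropped_loss(per_crop_probs, label: int, focal: bool = False,
                 focal_gamma: float = 2.0, eps: float = 1e-12) -> Tensor:
    """Loss of one trial from its k crop predictions.

    Averages the k per-crop class distributions, then scores the true class
    on the averaged distribution: negative log-likelihood by default, or the
    focal variant -(1-p)^gamma log p when ``focal`` is set.  With k=1 this is
    plain cross-entropy.
    """
    p = _lift(per_crop_probs)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("per_crop_probs must be a non-empty (k, n_c) array")
    if not 0 <= label < p.shape[1]:
        raise ValueError(f"label {label} out of range for {p.shape[1]} classes")
    p = _renormalize_rows(p, "crop predictions")
    avg = p.mean(axis=0)
    onehot = np.zeros(avg.shape[0])
    onehot[label] = 1.0
    p_true = (avg * Tensor(onehot)).sum() + eps
    nll = -p_true.log()
    if focal:
        return ((1.0 - p_true) ** focal_gamma) * nll
    return nll


def cropped_loss_batch(per_crop_probs, labels, focal: bool = False,
                       focal_gamma: float = 2.0, eps: float = 1e-12) -> Tensor:
    """Mean cropped loss over trials; probs (n, k, n_c), one label per trial."""
    p = _lift(per_crop_probs)
    labels = np.asarray(labels)
    n, _, n_c = p.shape
    p = _renormalize_rows(p, "crop predictions")
    avg = p.mean(axis=1)  # (n, n_c)
    onehot = np.zeros((n, n_c))
    onehot[np.arange(n), labels] = 1.0
    p_true = (avg * Tensor(onehot)).sum(axis=-1) + eps
    nll = -(p_true.log())
    if focal:
        nll = ((1.0 - p_true) ** focal_gamma) * nll
    return nll.mean()
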