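"""The four LEOPARD losses and their weighted combination.

All loss functions operate on either plain numpy arrays (returning floats,
useful for analysis and testing) or autodiff :class:`~leopard.nn.Tensor`
objects (returning scalar tensors, used by the training loop).

The total objective is

    L = w_con * L_con + w_rep * L_rep + w_rec * L_rec + w_adv * L_adv

with L_con the mean of NT-Xent contrastive losses computed separately on
content and temporal representations, L_rep the mean of the content and
temporal representation MSEs between actual and reconstructed data, L_rec
the masked reconstruction MSE, and L_adv a least-squares adversarial term
(targets: 1 = real, 0 = generated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, NumericError
from .nn import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "cosine_sim",
    "ntxent",
    "contrastive_loss",
    "representation_loss",
    "masked_reconstruction_loss",
    "mse",
    "adversarial_loss",
    "d_step_loss",
    "g_step_loss",
    "total_loss",
]


@dataclass
class LossWeights:
    """Weights of the four loss terms (defaults are the tuned optimum)."""

    w_rec: float = 1.0
    w_con: float = 0.1
    w_rep: float = 0.1
    w_adv: float = 1.0

    def __post_init__(self):
        if min(self.w_rec, self.w_con, self.w_rep, self.w_adv) < 0:
            raise ConfigError("loss weights must be non-negative")


def _is_tensor(*args) -> bool:
    return any(isinstance(a, Tensor) for a in args)


def _ret(value: Tensor, tensor_mode: bool):
    return value if tensor_mode else float(value.data)


def cosine_sim(a, b):
    """Cosine similarity a.b / (||a|| ||b||) of two non-zero vectors."""
    tensor_mode = _is_tensor(a, b)
    a, b = as_tensor(a), as_tensor(b)
    na = ((a * a).sum()) ** 0.5
    nb = ((b * b).sum()) ** 0.5
    if float(na.data) == 0.0 or float(nb.data) == 0.0:
        raise NumericError("cosine similarity undefined for zero vectors")
    return _ret((a * b).sum() / (na * nb), tensor_mode)


def _check_pairs(n: int, pairs) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ConfigError("positive_pairs must be an (N, 2) index array")
    flat = pairs.ravel()
    if len(set(flat.tolist())) != flat.size or flat.size != n:
        raise ConfigError("every embedding index must appear in exactly one pair")
    if flat.min() < 0 or flat.max() >= n:
        raise ConfigError("pair index out of range")
    return pairs


def ntxent(embeddings, positive_pairs, tau: float):
    """Normalized temperature-scaled cross-entropy over 2N embeddings.

    Per-anchor loss: -log[ exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau) ]
    with the positive partner j of anchor i and negatives spanning all other
    embeddings in the set; the returned value is the mean over all 2N anchors.
    """
    if tau <= 0:
        raise ConfigError("temperature must be positive")
    tensor_mode = _is_tensor(embeddings)
    z = as_tensor(embeddings)
    n = z.shape[0]
    pairs = _check_pairs(n, positive_pairs)
    partner = np.empty(n, dtype=int)
    partner[pairs[:, 0]] = pairs[:, 1]
    partner[pairs[:, 1]] = pairs[:, 0]

    norms = ((z * z).sum(axis=1, keepdims=True)) ** 0.5
    zn = z / norms
    sims = zn @ _transpose(zn)
    logits = sims * (1.0 / tau)
    not_self = 1.0 - np.eye(n)
    denom = (logits.exp() * not_self).sum(axis=1)
    pos = logits[(np.arange(n), partner)]
    loss = (denom.log() - pos).mean()
    return _ret(loss, tensor_mode)


def _transpose(t: Tensor) -> Tensor:
    data = t.data.T

    def bw(g):
        if t._needs():
            t._accumulate(g.T)

    return Tensor(data, parents=(t,), backward=bw)


def contrastive_loss(content_embeddings, content_pairs, temporal_embeddings,
                     temporal_pairs, tau: float):
    """Mean of the NT-Xent losses computed separately for the two representation kinds."""
    tensor_mode = _is_tensor(content_embeddings, temporal_embeddings)
    lc = ntxent(as_tensor(content_embeddings), content_pairs, tau)
    lt = ntxent(as_tensor(temporal_embeddings), temporal_pairs, tau)
    return _ret((lc + lt) * 0.5, tensor_mode)


def mse(a, b):
    """Elementwise mean squared error."""
    tensor_mode = _is_tensor(a, b)
    a, b = as_tensor(a), as_tensor(b)
    d = a - b
    return _ret((d * d).mean(), tensor_mode)


def representation_loss(content_real, content_recon, temporal_real, temporal_recon):
    """Mean of the content and temporal representation MSEs.

    The reconstructed-data representations are obtained by re-encoding
    generator outputs through the same encoders; this term stabilizes
    training by requiring actual and reconstructed data to factorize alike.
    """
    tensor_mode = _is_tensor(content_real, content_recon, temporal_real, temporal_recon)
    if as_tensor(content_real).shape != as_tensor(content_recon).shape or \
            as_tensor(temporal_real).shape != as_tensor(temporal_recon).shape:
        raise ConfigError("representation sets must be paired by sample")
    lc = mse(as_tensor(content_real), as_tensor(content_recon))
    lt = mse(as_tensor(temporal_real), as_tensor(temporal_recon))
    return _ret((as_tensor(lc) + as_tensor(lt)) * 0.5, tensor_mode)


def masked_reconstruction_loss(actual, reconstructed, imputation_mask=None):
    """MSE over cells *not* flagged by ``imputation_mask``.

    Mean-encoded cells carry no measurement; they are excluded from the
    reconstruction objective so that the model is never trained to reproduce
    fill-in values.
    """
    tensor_mode = _is_tensor(actual, reconstructed)
    actual_t = as_tensor(actual)
    recon_t = as_tensor(reconstructed)
    if actual_t.shape != recon_t.shape:
        raise ConfigError("actual and reconstructed shapes differ")
    if imputation_mask is None:
        keep = np.ones(actual_t.shape)
    else:
        imputation_mask = np.asarray(imputation_mask, dtype=bool)
        if imputation_mask.shape != actual_t.shape:
            raise ConfigError("imputation_mask shape differs from data shape")
        keep = (~imputation_mask).astype(np.float64)
    n_keep = keep.sum()
    if n_keep == 0:
        raise DataError("all cells are mean-encoded; reconstruction loss undefined")
    d = (recon_t - actual_t) * keep
    return _ret((d * d).sum() * (1.0 / n_keep), tensor_mode)


def d_step_loss(real_score, fake_score):
    """Least-squares discriminator loss at one head: (D(real)-1)^2 + D(fake)^2."""
    tensor_mode = _is_tensor(real_score, fake_score)
    r, f = as_tensor(real_score), as_tensor(fake_score)
    return _ret(((r - 1.0) ** 2).mean() + (f**2).mean(), tensor_mode)


def g_step_loss(fake_score):
    """Least-squares generator loss at one head: (D(fake)-1)^2."""
    tensor_mode = _is_tensor(fake_score)
    f = as_tensor(fake_score)
    return _ret(((f - 1.0) ** 2).mean(), tensor_mode)


def adversarial_loss(scores: dict, role: str, source_class):
    """Least-squares adversarial loss on the single head matching ``source_class``.

    ``scores`` maps each registered source class to ``(real_score, fake_score)``
    (the fake entry alone suffices for the generator step).  Heads other than
    ``source_class`` contribute zero.
    """
    if source_class not in scores:
        raise ConfigError(f"unknown source class {source_class!r}")
    real, fake = scores[source_class]
    if role == "discriminator-step":
        return d_step_loss(real, fake)
    if role == "generator-step":
        return g_step_loss(fake)
    raise ConfigError(f"unknown role {role!r}")


def total_loss(components, weights: LossWeights):
    """Weighted sum w_con*L_con + w_rep*L_rep + w_rec*L_rec + w_adv*L_adv."""
    l_rec, l_con, l_rep, l_adv = (components[k] for k in ("rec", "con", "rep", "adv"))
    for name, value in (("rec", l_rec), ("con", l_con), ("rep", l_rep), ("adv", l_adv)):
        v = value.data if isinstance(value, Tensor) else value
        if not np.all(np.isfinite(v)):
            raise NumericError(f"loss component {name!r} is non-finite")
    tensor_mode = _is_tensor(l_rec, l_con, l_rep, l_adv)
    out = (as_tensor(l_con) * weights.w_con + as_tensor(l_rep) * weights.w_rep
           + as_tensor(l_rec) * weights.w_rec + as_tensor(l_adv) * weights.w_adv)
    return _ret(out, tensor_mode)
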