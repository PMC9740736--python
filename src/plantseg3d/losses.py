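"""Training objective: attention-separation loss + cross-entropy.

The separation loss measures how similar the h attention heads of a module
are.  Each head's output matrix is flattened to a vector f_i and

    separation = -(1/h^2) * sum_{i != j} |<f_i, f_j>| / (||f_i|| * ||f_j||)

i.e. minus the h^2-normalised sum over ordered pairs of absolute cosine
similarities.  The value lives in [-(h-1)/h, 0]: the lower bound is attained
exactly when all heads are pairwise parallel (the collapse the loss exists
to penalise) and 0 when every pair is orthogonal.  The absolute value means
anti-parallel heads count as collapsed too.

Head diversity means driving this value toward 0, so the term enters the
combined objective as the non-negative *penalty* ``-separation``:

    total = cross_entropy + loss_scal * (-separation)

Gradient descent on the total therefore pushes pairwise head cosines down
(heads apart) while fitting the labels.  ``separation`` is averaged over all
attention modules of the network before weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .attention import HeadFeatures
from .errors import ValidationError

__all__ = ["LossBreakdown", "separation_loss", "separation_penalty",
           "cross_entropy_loss", "combined_loss"]

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _as_head_list(heads) -> list[Tensor]:
    if isinstance(heads, HeadFeatures):
        return heads.per_head
    return [h if isinstance(h, Tensor) else Tensor(np.asarray(h, dtype=float))
            for h in heads]


@dataclass
class LossBreakdown:
    """Components of one loss evaluation.

    ``separation`` is the (non-positive) separation loss;
    ``total = cross_entropy + loss_scal * (-separation)``.
    Fields are Tensors; the ``*_value`` properties give floats.
    """

    cross_entropy: Tensor
    separation: Tensor
    total: Tensor
    loss_scal: float

    @property
    def cross_entropy_value(self) -> float:
        return self.cross_entropy.item()

    @property
    def separation_value(self) -> float:
        return self.separation.item()

    @property
    def total_value(self) -> float:
        return self.total.item()


def separation_loss(heads) -> Tensor:
    """Head-diversity measure in [-(h-1)/h, 0]; see the module docstring.

    ``heads`` is a :class:`HeadFeatures` or a sequence of equal-shaped
    arrays/Tensors (one per head).  A head with (near-)zero norm contributes
    0 to every pair it appears in (logged).  Differentiable almost
    everywhere with respect to the head features.
    """
    hs = _as_head_list(heads)
    h = len(hs)
    if h < 2:
        raise ValidationError("separation loss needs at least 2 heads")
    shape = hs[0].shape
    if any(f.shape != shape for f in hs):
        raise ValidationError("head feature matrices must share one shape")
    flat = [f.reshape(-1) for f in hs]
    norms = [(f * f).sum() ** 0.5 for f in flat]
    dead = [i for i, nm in enumerate(norms) if nm.item() < _EPS]
    if dead:
        logger.warning("separation_loss: heads %s have ~zero norm; their "
                       "pair terms are treated as 0", dead)
    if len(dead) == h:
        raise ValidationError("all heads have zero norm")
    total = Tensor(0.0)
    for i in range(h):
        for j in range(h):
            if i == j or i in dead or j in dead:
                continue
            cos = (flat[i] * flat[j]).sum().abs() / (norms[i] * norms[j] + _EPS)
            total = total + cos
    return total * (-1.0 / h ** 2)


def separation_penalty(heads) -> Tensor:
    """The non-negative form (mean absolute pairwise cosine, h^2-normalised)
    that the combined objective minimises: ``-separation_loss(heads)``."""
    return separation_loss(heads) * -1.0


def _log_softmax(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    return shifted - shifted.exp().sum(axis=1, keepdims=True).log()


def cross_entropy_loss(logits, labels, mode: str = "categorical") -> Tensor:
    """Mean per-point classification loss.

    ``mode="categorical"`` (default): standard multi-class cross-entropy of
    the softmax distribution against one-hot targets.  ``mode="literal"``:
    the per-class binary sum  -[log q_y + sum_{c != y} log(1 - q_c)]  per
    point, averaged.  Both are 0 for a perfect one-hot prediction.
    """
    if hasattr(logits, "scores"):
        logits = logits.scores
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=float))
    labels = np.asarray(labels)
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValidationError(f"labels shape {labels.shape} != ({n},)")
    if labels.min() < 0 or labels.max() >= k:
        raise ValidationError("label outside class set")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    if mode == "categorical":
        logp = _log_softmax(logits)
        return -(logp * Tensor(onehot)).sum() / float(n)
    if mode == "literal":
        logp = _log_softmax(logits)
        q = logp.exp()
        log_1mq = (1.0 - q).clip_min(_EPS).log()
        per_point = -(logp * Tensor(onehot) + log_1mq * Tensor(1.0 - onehot))
        return per_point.sum() / float(n)
    raise ValidationError(f"unknown cross-entropy mode {mode!r}")


def combined_loss(logits, labels, heads_list, loss_scal: float = 1.0,
                  ce_mode: str = "categorical") -> LossBreakdown:
    """Total objective: cross-entropy plus ``loss_scal`` times the mean
    separation *penalty* over all attention modules.

    With ``loss_scal = 0`` the total is exactly the cross-entropy; with all
    modules' heads mutually orthogonal the separation term vanishes and the
    total again equals the cross-entropy.
    """
    if not heads_list:
        raise ValidationError("heads_list must contain at least one module")
    ce = cross_entropy_loss(logits, labels, mode=ce_mode)
    sep = Tensor(0.0)
    for heads in heads_list:
        sep = sep + separation_loss(heads)
    sep = sep / float(len(heads_list))
    total = ce + sep * (-float(loss_scal))
    return LossBreakdown(ce, sep, total, float(loss_scal))
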