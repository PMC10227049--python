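"""Composite training objective for quantile retention-time learning.

The objective combines, per batch of size N:

* squared error on the point prediction (mean),
* pinball (quantile) loss for the 90th and 10th percentile heads,
* ordering penalties ``ReLU(y10 - pred)`` and ``ReLU(pred - y90)``
  that softly enforce ``y10 <= pred <= y90``,
* a dead-time penalty ``ReLU(t0 - pred)`` keeping predictions above the
  physical lower bound of RTv (default 2 min·mL/min).

The pinball loss is the standard nonnegative form
``mean(0.01a·ReLU(u) + (1 - 0.01a)·ReLU(-u))`` with residual
``u = y_true - y_quantile``: under-prediction of the a-th percentile is
weighted ``0.01a``, over-prediction ``1 - 0.01a``.  All quantile and
penalty terms are batch means so the term scales stay comparable.

Every function accepts either numpy arrays or autograd tensors; with
tensors the result participates in backpropagation (ReLU subgradient 0
at the kinks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, relu
from .constants import DEADTIME_RTV
from .errors import ContractError

TERM_NAMES = ("mse", "pinball_90", "pinball_10", "order_low", "order_high", "deadtime")


@dataclass
class LossConfig:
    alphas: tuple[float, float] = (10.0, 90.0)
    deadtime_rtv: float = DEADTIME_RTV
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for a in self.alphas:
            if not 0.0 < a < 100.0:
                raise ContractError(f"quantile alpha must be in (0, 100), got {a}")
        if self.deadtime_rtv <= 0:
            raise ContractError("deadtime_rtv must be positive")

    def weight(self, term: str) -> float:
        return float(self.weights.get(term, 1.0))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.atleast_1d(np.asarray(x, float)))


def pinball(y_true, y_alpha, alpha: float):
    """Mean pinball loss of the alpha-th percentile prediction.

    Nonnegative, zero iff ``y_true == y_alpha`` elementwise; its
    constant minimizer over a sample is the empirical alpha-quantile.
    """
    if not 0.0 < alpha < 100.0:
        raise ContractError(f"alpha must be in (0, 100), got {alpha}")
    t, q = _wrap(y_true), _wrap(y_alpha)
    tau = 0.01 * alpha
    u = t - q
    loss = (tau * relu(u) + (1.0 - tau) * relu(-1.0 * u)).mean()
    return loss if isinstance(y_alpha, Tensor) or isinstance(y_true, Tensor) else float(loss.data)


def loss_terms(y_true, q10, pred, q90, config: LossConfig | None = None) -> dict:
    """The six weighted terms of the composite objective, as tensors."""
    config = config or LossConfig()
    t = _wrap(y_true)
    q10, pred, q90 = _wrap(q10), _wrap(pred), _wrap(q90)
    if t.data.size == 0:
        raise ContractError("empty batch")
    if not (t.data.shape == q10.data.shape == pred.data.shape == q90.data.shape):
        raise ContractError("batch shapes differ")
    a_lo, a_hi = sorted(config.alphas)
    terms = {
        "mse": ((t - pred) * (t - pred)).mean(),
        "pinball_90": pinball(t, q90, a_hi),
        "pinball_10": pinball(t, q10, a_lo),
        "order_low": relu(q10 - pred).mean(),
        "order_high": relu(pred - q90).mean(),
        "deadtime": relu(config.deadtime_rtv - pred).mean(),
    }
    return {k: config.weight(k) * v for k, v in terms.items()}


def total_loss(batch_true, batch_pred, config: LossConfig | None = None):
    """Composite loss for a batch of quantile predictions.

    ``batch_pred`` is a sequence of objects with ``q10``/``pred``/``q90``
    attributes (or a [N, 3] array in that column order).  Returns
    ``(total, per_term)`` as plain floats.
    """
    y_true = np.atleast_1d(np.asarray(batch_true, float))
    arr = _prediction_array(batch_pred)
    if arr.shape[0] != y_true.shape[0]:
        raise ContractError("batch_true and batch_pred lengths differ")
    terms = loss_terms(y_true, arr[:, 0], arr[:, 1], arr[:, 2], config)
    per_term = {k: float(v.data) for k, v in terms.items()}
    return sum(per_term.values()), per_term


def _prediction_array(batch_pred) -> np.ndarray:
    if hasattr(batch_pred, "ndim"):
        arr = np.asarray(batch_pred, float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ContractError("prediction array must have shape [N, 3]")
        return arr
    rows = [[p.q10, p.pred, p.q90] for p in batch_pred]
    if not rows:
        raise ContractError("empty batch")
    return np.asarray(rows, float)
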