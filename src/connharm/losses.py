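"""The four training objectives and their weighted combination.

* ``L_C`` — mean cross-entropy over the labelled subjects only.
* ``L_L`` — Gaussian negative log-likelihood of the input given its
  reconstruction, with a fixed per-feature scale ``sigma``:
  ``(1/2N) Σ_j Σ_v [ log(2π σ_v²) + (x_jv − x̂_jv)² / (2 σ_v²) ]``.
* ``L_D`` — KL divergence of the latent posterior N(z_mu, z_sigma²) from the
  standard-normal prior: ``(1/2N) Σ_j Σ_d [ z_sigma² + z_mu² − 2 log z_sigma − 1 ]``.
* ``L_R`` — site-effect reconstruction objective.  With ``θ_jv = x_jv − α_v``:
  ``(1/2N) Σ_j Σ_v ½ [ log(2π σ_v²) + θ²/(2σ_v²) + log(2π δ_iv²) + (θ − γ_iv)²/(2δ_iv²) ]``,
  i.e. the joint negative log-likelihood of x under N(α_v, σ_v²) and of θ
  under N(γ_iv, δ_iv²).  Because γ and δ here are the *live* site-effect
  parameters, this term is what pulls the learnable harmonisation layers
  toward the least-squares location/scale solution.

The joint loss is ``L = L_C + γ1·L_L + γ2·L_D + γ3·L_R`` with absent terms
contributing zero.  All functions accept either numpy arrays (returning a
float) or autograd :class:`~connharm.autograd.Tensor` inputs (returning a
Tensor so gradients flow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

log = logging.getLogger(__name__)

PROB_FLOOR = 1e-12
LOG_2PI = float(np.log(2.0 * np.pi))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _maybe_float(out: Tensor, *inputs):
    if any(isinstance(i, Tensor) for i in inputs):
        return out
    return out.item()


def cross_entropy_loss(y_hat, y_onehot):
    """Mean cross-entropy over labelled subjects.

    ``y_hat`` are class probabilities (rows summing to one), ``y_onehot`` the
    one-hot true labels.  Probabilities are floored at 1e-12 inside the log;
    the floor firing is logged since it signals a saturated classifier.
    """
    y_onehot = np.atleast_2d(np.asarray(y_onehot, dtype=float))
    if y_onehot.shape[0] == 0:
        raise ValueError("cross-entropy needs at least one labelled subject")
    yh = _as_tensor(y_hat)
    raw = np.atleast_2d(yh.data)
    if np.any((raw < PROB_FLOOR) & (y_onehot > 0)):
        log.warning("probability floor %.0e triggered in cross-entropy", PROB_FLOOR)
    n = y_onehot.shape[0]
    floored = yh * (1.0 - PROB_FLOOR) + PROB_FLOOR  # keeps grad; lifts exact zeros
    out = (Tensor(y_onehot) * floored.log()).sum() * (-1.0 / n)
    return _maybe_float(out, y_hat)


def cross_entropy_from_logits(logits: Tensor, y_idx: np.ndarray):
    """Numerically stable cross-entropy used by the training loop."""
    y_idx = np.asarray(y_idx, dtype=int)
    if y_idx.size == 0:
        raise ValueError("cross-entropy needs at least one labelled subject")
    logp = _as_tensor(logits).log_softmax(axis=-1)
    onehot = np.zeros(np.atleast_2d(logp.data).shape)
    onehot[np.arange(y_idx.size), y_idx] = 1.0
    out = (Tensor(onehot) * logp).sum() * (-1.0 / y_idx.size)
    return _maybe_float(out, logits)


def likelihood_loss(x, x_hat, sigma):
    """Gaussian NLL of x given reconstruction x_hat with fixed scale sigma."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    xt, xh = _as_tensor(x), _as_tensor(x_hat)
    n = xt.data.shape[0] if xt.data.ndim > 1 else 1
    const = float(np.sum(LOG_2PI + 2.0 * np.log(sigma))) * n
    quad = (((xt - xh) ** 2) / (2.0 * sigma**2)).sum()
    out = (quad + const) * (1.0 / (2.0 * n))
    return _maybe_float(out, x, x_hat)


def kl_loss(z_mu, z_sigma):
    """KL(N(z_mu, z_sigma²) || N(0, I)), averaged over subjects (×1/2)."""
    zs = _as_tensor(z_sigma)
    if np.any(zs.data <= 0):
        raise ValueError("z_sigma must be strictly positive")
    zm = _as_tensor(z_mu)
    n = np.atleast_2d(zm.data).shape[0] if zm.data.ndim > 1 else 1
    out = (zs**2 + zm**2 - zs.log() * 2.0 - 1.0).sum() * (1.0 / (2.0 * n))
    return _maybe_float(out, z_mu, z_sigma)


def reconstruction_loss(x, alpha, gamma, delta, sigma):
    """Site-effect reconstruction objective (see module docstring).

    ``gamma`` and ``delta`` are the per-subject site-effect rows (broadcastable
    against x); gradients flow into them when they are Tensors.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    dt = _as_tensor(delta)
    if np.any(dt.data <= 0):
        raise ValueError("delta must be strictly positive")
    xt, at, gt = _as_tensor(x), _as_tensor(alpha), _as_tensor(gamma)
    xb = np.atleast_2d(xt.data)
    n, v = xb.shape
    theta = xt - at
    term_sigma = theta**2 / (2.0 * sigma**2)
    term_delta = (theta - gt) ** 2 / (dt**2 * 2.0) + (dt**2 * 2.0 * np.pi).log()
    const_sigma = float(np.sum(LOG_2PI + 2.0 * np.log(sigma))) * n
    out = (term_sigma.sum() + term_delta.sum() + const_sigma) * (1.0 / (4.0 * n))
    return _maybe_float(out, x, alpha, gamma, delta)


@dataclass
class LossBreakdown:
    """Per-term values of the joint objective (floats, for logging)."""

    l_c: float | None
    l_l: float | None
    l_d: float | None
    l_r: float | None
    gamma1: float
    gamma2: float
    gamma3: float
    total: float

    def as_row(self) -> dict:
        return {"L_C": self.l_c, "L_L": self.l_l, "L_D": self.l_d,
                "L_R": self.l_r, "total": self.total}


def joint_loss(l_c=None, l_l=None, l_d=None, l_r=None, *,
               gamma1: float = 1e-5, gamma2: float = 1e-3, gamma3: float = 1e-4):
    """Weighted combination L = L_C + γ1 L_L + γ2 L_D + γ3 L_R.

    Terms passed as ``None`` (unavailable for the variant or an unlabelled
    batch) contribute zero.  Returns ``(total, LossBreakdown)`` where the
    total preserves Tensor-ness for backprop.
    """
    if min(gamma1, gamma2, gamma3) < 0:
        raise ValueError("loss weights must be nonnegative")
    total = None
    for term, w in ((l_c, 1.0), (l_l, gamma1), (l_d, gamma2), (l_r, gamma3)):
        if term is None:
            continue
        piece = term * w
        total = piece if total is None else total + piece
    if total is None:
        raise ValueError("at least one loss term must be provided")

    def _f(t):
        return None if t is None else (t.item() if isinstance(t, Tensor) else float(t))

    breakdown = LossBreakdown(
        l_c=_f(l_c), l_l=_f(l_l), l_d=_f(l_d), l_r=_f(l_r),
        gamma1=gamma1, gamma2=gamma2, gamma3=gamma3,
        total=total.item() if isinstance(total, Tensor) else float(total))
    return total, breakdown
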