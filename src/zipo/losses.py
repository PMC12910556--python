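"""Zero-inflated likelihood and the full training loss.

The observation model for a count ``x`` with dropout probability
``z = sigmoid(r)``, rate ``m = l·μ`` and (optionally) dispersion ``θ`` is the
mixture ``z·δ0(x) + (1−z)·exp f(x; m, θ)`` where ``f`` is the Poisson or
negative-binomial log-density. Taking logs naively requires ``log`` of a sum of
probabilities that under/overflows for extreme logits. Rearranging instead
gives a form built entirely from the composite ``log sig`` function,

    log L = Σ log sig(−r)
          + Σ_{x=0} [ r − log sig(r − f(0; m, θ)) ]
          + Σ_{x>0} f(x; m, θ),

which is evaluated here through the stable identity
``log sig(t) = −softplus(−t)`` with a piecewise-stable softplus — no truncation
or offset constants anywhere.

The training loss adds an L2 penalty on the predicted zero probabilities
(strength ``α_z``), the scale-invariant L1/L2 penalty on the first encoding
layer's weights (``α_w``), an optional L2 penalty on the dispersion (``α_θ``),
and, for the negative binomial only, a small auxiliary penalty
``0.1·E[(l_c − Σ_g x_cg)²]`` tying the predicted totals to the observed
library sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from ._autodiff import Tensor, logaddexp
from .exceptions import NumericError, ValidationError
from .model import CellDistribution, ModelSpec

__all__ = [
    "LossBreakdown",
    "poisson_log_pmf",
    "nb_log_pmf",
    "zi_log_likelihood",
    "scale_invariant_weight_penalty",
    "total_loss",
]

ZINB_RATE_PENALTY_WEIGHT = 0.1


@dataclass
class LossBreakdown:
    """Additive components of the training objective."""

    nll: float
    zero_penalty: float
    weight_penalty: float
    theta_penalty: float
    rate_penalty: float

    @property
    def total(self) -> float:
        return (
            self.nll
            + self.zero_penalty
            + self.weight_penalty
            + self.theta_penalty
            + self.rate_penalty
        )

    def validate(self) -> None:
        for name in ("nll", "zero_penalty", "weight_penalty", "theta_penalty",
                     "rate_penalty"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise NumericError(f"non-finite loss term {name!r}: {v}")

    def as_dict(self) -> dict:
        return {
            "nll": self.nll,
            "zero_penalty": self.zero_penalty,
            "weight_penalty": self.weight_penalty,
            "theta_penalty": self.theta_penalty,
            "rate_penalty": self.rate_penalty,
            "total": self.total,
        }


def _check_counts(x) -> np.ndarray:
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValidationError("counts must be non-negative")
    if not np.issubdtype(x.dtype, np.integer):
        if np.any(x != np.floor(x)):
            raise ValidationError("counts must be integers")
    return x.astype(np.float64)


def poisson_log_pmf(x, log_m):
    """Poisson log-density ``x·log m − m − log Γ(x+1)`` (vectorized)."""
    x = _check_counts(x)
    log_m = np.asarray(log_m, dtype=np.float64)
    return x * log_m - np.exp(log_m) - gammaln(x + 1.0)


def nb_log_pmf(x, log_m, log_theta):
    """Negative-binomial log-density with mean ``m`` and dispersion ``θ``.

    Parameterized so variance = m + m²/θ; converges to Poisson as θ → ∞.
    """
    x = _check_counts(x)
    log_m = np.asarray(log_m, dtype=np.float64)
    log_theta = np.asarray(log_theta, dtype=np.float64)
    theta = np.exp(log_theta)
    log_theta_plus_m = np.logaddexp(log_theta, log_m)
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (log_theta - log_theta_plus_m)
        + x * (log_m - log_theta_plus_m)
    )


def _log_sigmoid(t: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -t)


def zi_log_likelihood(x, dist: CellDistribution) -> float:
    """Mean zero-inflated log-likelihood per cell, in the stable form."""
    x = _check_counts(x)
    if x.shape != dist.r.shape:
        raise ValidationError(
            f"counts shape {x.shape} does not match distribution {dist.r.shape}"
        )
    log_m = dist.log_l[:, None] + dist.log_mu
    if dist.log_theta is None:
        f0 = -np.exp(log_m)
        f_pos = poisson_log_pmf(x, log_m)
    else:
        theta = np.exp(dist.log_theta)
        f0 = theta * (dist.log_theta - np.logaddexp(dist.log_theta, log_m))
        f_pos = nb_log_pmf(x, log_m, dist.log_theta)
    r = dist.r
    zero = x == 0
    total = _log_sigmoid(-r).sum()
    total += (r[zero] - _log_sigmoid(r[zero] - f0[zero])).sum()
    total += f_pos[~zero].sum()
    result = total / x.shape[0]
    if not np.isfinite(result):
        raise NumericError("non-finite zero-inflated log-likelihood")
    return float(result)


def scale_invariant_weight_penalty(W) -> float:
    """Mean over first-layer neurons of (mean |w|) / sqrt(mean w²).

    ``W`` is neurons × genes. Dividing L1 by L2 makes the term invariant to
    rescaling a neuron's weights (which batch normalization could otherwise
    absorb); each row's value lies in [1/√G, 1] and shrinks as the row becomes
    sparser. An all-zero row contributes 0 with a warning.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] < 1:
        raise ValidationError("W must be a neurons × genes matrix")
    mean_abs = np.abs(W).mean(axis=1)
    rms = np.sqrt((W ** 2).mean(axis=1))
    zero_rows = rms == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero row(s) in first-layer weights "
            "contribute 0 to the sparsity penalty",
            stacklevel=2,
        )
    terms = np.where(zero_rows, 0.0, mean_abs / np.where(zero_rows, 1.0, rms))
    return float(terms.mean())


def total_loss(x, dist: CellDistribution, W, spec: ModelSpec) -> LossBreakdown:
    """Evaluate all loss terms for fixed (non-training) predictions."""
    x = _check_counts(x)
    nll = -zi_log_likelihood(x, dist)
    z = expit(dist.r)
    zero_penalty = spec.alpha_z * float((z ** 2).mean())
    weight_penalty = spec.alpha_w * scale_invariant_weight_penalty(W)
    if spec.distribution == "zinb":
        if dist.log_theta is None:
            raise ValidationError("zinb loss requires log_theta")
        theta = np.exp(dist.log_theta)
        theta_penalty = spec.alpha_theta * float((theta ** 2).mean())
        lib = x.sum(axis=1)
        rate_penalty = ZINB_RATE_PENALTY_WEIGHT * float(
            ((np.exp(dist.log_l) - lib) ** 2).mean()
        )
    else:
        theta_penalty = 0.0
        rate_penalty = 0.0
    bd = LossBreakdown(nll, zero_penalty, weight_penalty, theta_penalty, rate_penalty)
    bd.validate()
    return bd


# -- autodiff-tape versions used by the training loop -------------------------


def zi_log_likelihood_t(x: np.ndarray, out: dict, distribution: str) -> Tensor:
    """Tape version of :func:`zi_log_likelihood` over a batch (mean per cell)."""
    x = _check_counts(x)
    zero_mask = (x == 0).astype(np.float64)
    pos_mask = 1.0 - zero_mask
    log_l, r, log_mu = out["log_l"], out["r"], out["log_mu"]
    log_m = log_l.reshape(-1, 1) + log_mu
    if distribution == "zip":
        m = log_m.exp()
        f0 = -m
        f = Tensor(x) * log_m - m - Tensor(gammaln(x + 1.0))
    else:
        log_theta = out["log_theta"]
        theta = log_theta.exp()
        log_tpm = logaddexp(log_theta, log_m)
        f0 = theta * (log_theta - log_tpm)
        f = (
            (Tensor(x) + theta).lgamma()
            - theta.lgamma()
            - Tensor(gammaln(x + 1.0))
            + theta * (log_theta - log_tpm)
            + Tensor(x) * (log_m - log_tpm)
        )
    term_all = (-r).log_sigmoid().sum()
    term_zero = ((r - (r - f0).log_sigmoid()) * Tensor(zero_mask)).sum()
    term_pos = (f * Tensor(pos_mask)).sum()
    return (term_all + term_zero + term_pos) * (1.0 / x.shape[0])


def weight_penalty_t(W: Tensor) -> Tensor:
    """Tape version of the scale-invariant penalty.

    ``W`` is stored genes × neurons (fan_in × fan_out); the per-neuron terms
    therefore reduce over axis 0. A vanishing-norm guard keeps the gradient
    finite; it is far below any trained weight scale.
    """
    mean_abs = W.abs().mean(axis=0)
    mean_sq = (W * W).mean(axis=0)
    return (mean_abs * (mean_sq + 1e-300) ** -0.5).mean()


def total_loss_t(
    x: np.ndarray, out: dict, W: Tensor, spec: ModelSpec
) -> tuple[Tensor, LossBreakdown]:
    """Full training objective on the tape plus its numeric breakdown."""
    x = _check_counts(x)
    nll = -zi_log_likelihood_t(x, out, spec.distribution)
    z = out["r"].sigmoid()
    zero_pen = (z * z).mean() * spec.alpha_z
    weight_pen = weight_penalty_t(W) * spec.alpha_w
    total = nll + zero_pen + weight_pen
    theta_pen_val = 0.0
    rate_pen_val = 0.0
    if spec.distribution == "zinb":
        theta = out["log_theta"].exp()
        theta_pen = (theta * theta).mean() * spec.alpha_theta
        lib = x.sum(axis=1)
        diff = out["log_l"].exp() - Tensor(lib)
        rate_pen = (diff * diff).mean() * ZINB_RATE_PENALTY_WEIGHT
        total = total + theta_pen + rate_pen
        theta_pen_val = theta_pen.item()
        rate_pen_val = rate_pen.item()
    bd = LossBreakdown(
        nll.item(), zero_pen.item(), weight_pen.item(), theta_pen_val, rate_pen_val
    )
    bd.validate()
    return total, bd
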