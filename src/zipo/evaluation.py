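"""Evaluation metrics and multi-seed model comparison.

Model comparisons follow the multi-seed protocol: train each candidate with a
set of random seeds (12 by default), summarize each by the mean loss and its
standard error, and draw error bars of half-width λ·SEM with
λ = Φ⁻¹(confidence)/√2 (≈1.64 at 99%). Under normality and equal variances,
non-overlapping bars for two models correspond to rejecting equality at the
stated one-sided confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .exceptions import ValidationError
from .model import CellDistribution

__all__ = [
    "ComparisonSummary",
    "rate_mse",
    "mean_zero_probability",
    "error_bar_lambda",
    "compare_models",
]


def rate_mse(x, dist: CellDistribution) -> float:
    """Mean squared error between predicted rates ``m = l·μ`` and raw counts."""
    x = np.asarray(x.values if hasattr(x, "values") else x)
    m = dist.mean_rate()
    if x.shape != m.shape:
        raise ValidationError(
            f"counts shape {x.shape} does not match rates {m.shape}"
        )
    return float(((m - x) ** 2).mean())


def mean_zero_probability(dist: CellDistribution) -> float:
    """Mean predicted dropout probability, mean over entries of sigmoid(r)."""
    return float(expit(dist.r).mean())


def error_bar_lambda(confidence: float = 0.99, denominator: str = "sqrt2") -> float:
    """Error-bar multiplier λ = Φ⁻¹(confidence)/√2.

    ``denominator="two"`` selects the literal /2 variant (≈1.163 at 99%)
    instead of the /√2 form that yields the conventional ≈1.64.
    """
    if not (0 < confidence < 1):
        raise ValidationError("confidence must lie in (0, 1)")
    if denominator == "sqrt2":
        d = np.sqrt(2.0)
    elif denominator == "two":
        d = 2.0
    else:
        raise ValidationError("denominator must be 'sqrt2' or 'two'")
    return float(norm.ppf(confidence) / d)


@dataclass
class ComparisonSummary:
    model_label: str
    per_seed_losses: list
    mean: float
    sem: float
    lambda_: float
    bar_halfwidth: float
    separated_from: list = field(default_factory=list)

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mean - self.bar_halfwidth, self.mean + self.bar_halfwidth)


def compare_models(
    per_model_losses: dict,
    confidence: float = 0.99,
    denominator: str = "sqrt2",
) -> list[ComparisonSummary]:
    """Summarize per-seed losses per model and flag separated pairs.

    Two models are "separated" when their ``mean ± λ·SEM`` intervals do not
    overlap. SEM uses the sample standard deviation (ddof=1) over seeds.
    """
    lam = error_bar_lambda(confidence, denominator)
    summaries = []
    for label, losses in per_model_losses.items():
        losses = [float(v) for v in losses]
        if len(losses) < 2:
            raise ValidationError(
                f"model {label!r} needs >= 2 per-seed losses, got {len(losses)}"
            )
        mean = float(np.mean(losses))
        sem = float(np.std(losses, ddof=1) / np.sqrt(len(losses)))
        summaries.append(
            ComparisonSummary(label, losses, mean, sem, lam, lam * sem)
        )
    for a, b in combinations(summaries, 2):
        lo_a, hi_a = a.interval
        lo_b, hi_b = b.interval
        if hi_a < lo_b or hi_b < lo_a:
            a.separated_from.append(b.model_label)
            b.separated_from.append(a.model_label)
    return summaries
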