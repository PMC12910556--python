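"""First-layer weight normalization, thresholded pruning, and its sensitivity.

Each first-layer neuron's weights are normalized by the row's maximum absolute
value (so relative magnitudes within a neuron are what counts — batch
normalization can absorb any overall scale), and entries whose normalized
magnitude falls below a threshold δ are set to exactly zero in the underlying
weights. The report records the pruned fraction and the change in validation
NLL and rate MSE on a supplied evaluation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import PreprocessSpec
from .exceptions import ValidationError
from .losses import zi_log_likelihood
from .model import ZiPoNetwork
from .training import _resolve_inputs

__all__ = ["PruneReport", "normalize_weights", "prune"]


@dataclass
class PruneReport:
    delta: float
    fraction_pruned: float
    nll_before: float
    nll_after: float
    mse_before: float
    mse_after: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def normalize_weights(W) -> np.ndarray:
    """Divide each neuron's weights by the row's maximum absolute value.

    Every nonzero row attains ±1 at its largest-magnitude entry; all-zero rows
    are left as zeros with a warning.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2:
        raise ValidationError("W must be a neurons × genes matrix")
    row_max = np.abs(W).max(axis=1, keepdims=True)
    zero_rows = row_max.ravel() == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero row(s) left unnormalized",
            stacklevel=2,
        )
    return W / np.where(row_max == 0, 1.0, row_max)


def prune(
    model: ZiPoNetwork,
    delta: float,
    X_eval,
    covariates=None,
    preprocess_spec: PreprocessSpec | None = None,
) -> tuple[ZiPoNetwork, PruneReport]:
    """Zero out first-layer weights with normalized magnitude below ``delta``.

    Pruning is permanent (in place on the model's weights). The report compares
    per-cell validation NLL and rate MSE on ``X_eval`` before and after.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValidationError("delta must lie in [0, 1]")
    counts, inputs, cov = _resolve_inputs(X_eval, covariates, preprocess_spec)

    def _metrics():
        _, dist = model.predict(inputs, cov)
        nll = -zi_log_likelihood(counts, dist)
        mse = float(((dist.mean_rate() - counts) ** 2).mean())
        return nll, mse

    nll_before, mse_before = _metrics()
    W_param = model.first_layer_weight_tensor()  # stored genes × neurons
    W_rows = W_param.data.T  # neurons × genes view
    normalized = normalize_weights(W_rows)
    mask = np.abs(normalized) < delta
    W_rows[mask] = 0.0
    nll_after, mse_after = _metrics()
    report = PruneReport(
        delta=float(delta),
        fraction_pruned=float((W_rows == 0).mean()),
        nll_before=nll_before,
        nll_after=nll_after,
        mse_before=mse_before,
        mse_after=mse_after,
    )
    return model, report
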