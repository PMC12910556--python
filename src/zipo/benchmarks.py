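"""Reference benchmark experiments on synthetic data.

These routines bundle the package's standard self-checks so they can be run
identically from the test suite, the acceptance script, or a shell:

* :func:`library_size_recovery` — train on a simulated zero-inflated Poisson
  dataset and measure how well the predicted library sizes and log rates
  recover the generating truth.
* :func:`zero_inflation_dose_response` — train across a ladder of zero-
  probability regularization strengths α_z and record the mean predicted
  dropout probability (expected to fall as α_z grows).
* :func:`sparsity_dose_response` — train across weight-regularization
  strengths α_w on a sparse dataset and record the fraction of small
  (max-normalized) first-layer weights, plus the effect of pruning at a
  threshold δ.

Problem sizes are desk-scale: a few thousand cells and a few hundred genes,
with training budgets of 40–300 epochs depending on what the experiment
measures (weight sparsification accumulates over optimizer steps and therefore
gets the longest schedule, with plateau reductions disabled so the step size
stays at the target rate).
"""

from __future__ import annotations

import numpy as np

from .data import PreprocessSpec
from .evaluation import mean_zero_probability
from .model import ModelSpec, build_model
from .simulate import SimSpec, simulate
from .sparsify import normalize_weights, prune
from .training import TrainConfig, impute, train

__all__ = [
    "library_size_recovery",
    "zero_inflation_dose_response",
    "sparsity_dose_response",
]

LOG_INPUT = PreprocessSpec(log_transform=True)


def library_size_recovery(seed: int = 3, max_epochs: int = 160) -> dict:
    """Parameter recovery on a 2000-cell × 300-gene ZIP simulation.

    Trains a 256-128-64-32 encoder with full residuals and α_z = 0.1 on
    log1p inputs; returns Pearson correlations between predicted and true
    library sizes, and between predicted and true log rates on entries with
    observed positive counts.
    """
    cm, truth = simulate(
        SimSpec(n_cells=2000, n_genes=300, n_factors=4, seed=seed)
    )
    spec = ModelSpec(encoder_sizes=[256, 128, 64, 32], n_genes=300,
                     residuals="full", alpha_z=0.1)
    model = build_model(spec, seed=seed)
    result = train(model, cm, cfg=TrainConfig(max_epochs=max_epochs, seed=seed),
                   preprocess_spec=LOG_INPUT)
    dist = impute(model, cm, preprocess_spec=LOG_INPUT)
    lib_r = float(np.corrcoef(np.exp(dist.log_l), truth.true_l)[0, 1])
    log_m = dist.log_l[:, None] + dist.log_mu
    true_log_m = np.log(truth.true_l[:, None] * truth.true_mu)
    pos = cm.values > 0
    rate_r = float(np.corrcoef(log_m[pos], true_log_m[pos])[0, 1])
    return {
        "library_size_pearson_r": lib_r,
        "log_rate_pearson_r": rate_r,
        "best_validation_loss": result.best_validation_loss,
        "epochs_run": result.epochs_run,
        "n_cells": 2000,
        "n_genes": 300,
    }


def zero_inflation_dose_response(
    alphas=(0.0, 0.1, 10.0, 1e4, 1e8),
    data_seed: int = 5,
    train_seed: int = 7,
    max_epochs: int = 40,
) -> dict:
    """Mean predicted dropout probability across a ladder of α_z values,
    trained on the same 600 × 150 simulation and seed throughout."""
    cm, _ = simulate(SimSpec(n_cells=600, n_genes=150, seed=data_seed))
    mean_z = {}
    for alpha_z in alphas:
        spec = ModelSpec(encoder_sizes=[64, 32, 16], n_genes=150,
                         residuals="full", alpha_z=alpha_z)
        model = build_model(spec, seed=train_seed)
        train(model, cm, cfg=TrainConfig(max_epochs=max_epochs, seed=train_seed),
              preprocess_spec=LOG_INPUT)
        dist = impute(model, cm, preprocess_spec=LOG_INPUT)
        mean_z[alpha_z] = mean_zero_probability(dist)
    return {"alphas": list(alphas), "mean_zero_probability": mean_z,
            "n_cells": 600, "n_genes": 150}


def sparsity_dose_response(
    alphas=(0.0, 0.01, 0.1, 1.0),
    delta: float = 1e-4,
    small_threshold: float = 0.01,
    data_seed: int = 5,
    train_seed: int = 7,
    max_epochs: int = 300,
) -> dict:
    """Small-weight fractions across α_w, plus pruning impact at ``delta``.

    The dataset is a 2000 × 200 simulation at the sparse end of realistic UMI
    data (~2–3% nonzero entries), where many genes are rarely detected and
    their first-layer weights receive data gradients too weak to resist the
    sparsity penalty — the regime in which the scale-invariant term visibly
    reshapes the first layer within a desk-scale step budget. Raw counts feed
    the encoder, plateau reductions are disabled and early stopping is off so
    every run takes the same number of optimizer steps.
    """
    cm, _ = simulate(
        SimSpec(n_cells=2000, n_genes=200, lib_log_mean=1.5, seed=data_seed)
    )
    cfg = TrainConfig(max_epochs=max_epochs, batch_size=32,
                      early_stop_epochs=max_epochs, plateau_factor=1.0,
                      seed=train_seed)
    small_fraction = {}
    prune_reports = {}
    for alpha_w in alphas:
        spec = ModelSpec(encoder_sizes=[64, 32, 16], n_genes=200,
                         residuals="full", alpha_w=alpha_w)
        model = build_model(spec, seed=train_seed)
        train(model, cm, cfg=cfg)
        W_norm = normalize_weights(model.first_layer_weights())
        small_fraction[alpha_w] = float((np.abs(W_norm) < small_threshold).mean())
        if alpha_w in (0.0, 0.1):
            _, report = prune(model, delta, cm)
            prune_reports[alpha_w] = report
    return {
        "alphas": list(alphas),
        "small_weight_fraction": small_fraction,
        "prune_reports": prune_reports,
        "n_cells": 2000,
        "n_genes": 200,
    }
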