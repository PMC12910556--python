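"""Hyperparameter search over encoder structures and regularization strengths.

The search space defaults to the five candidate encoder structures
(2048-1024-512-256-128 down to 512-256-128-64), all with full residual
connections, and log-uniform sampling of α_z and α_w over [0.01, 1]. The
objective is the best validation total loss of a trained model; the sampler is
pluggable (random or grid here — any callable with the same interface works).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ValidationError, ZipoError
from .model import ModelSpec, build_model
from .training import TrainConfig, train

__all__ = [
    "SearchSpace",
    "TrialRecord",
    "RandomSampler",
    "GridSampler",
    "run_search",
]

DEFAULT_STRUCTURES = (
    "2048-1024-512-256-128",
    "1024-512-256-128",
    "1024-512-256-128-64",
    "512-256-128",
    "512-256-128-64",
)


def parse_structure(s: str) -> list[int]:
    """Parse an ``s1-s2-...-sp`` structure string into layer sizes."""
    try:
        sizes = [int(tok) for tok in str(s).replace("–", "-").split("-")]
    except ValueError as exc:
        raise ValidationError(f"malformed structure string {s!r}") from exc
    if not sizes or any(v < 1 for v in sizes):
        raise ValidationError(f"malformed structure string {s!r}")
    return sizes


@dataclass
class SearchSpace:
    encoder_structures: Sequence[str] = DEFAULT_STRUCTURES
    alpha_z_range: tuple[float, float] = (0.01, 1.0)
    alpha_w_range: tuple[float, float] = (0.01, 1.0)
    n_trials: int = 96
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.alpha_z_range, self.alpha_w_range):
            if not (0 < lo < hi):
                raise ValidationError("ranges must satisfy 0 < low < high")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be positive")
        if not self.encoder_structures:
            raise ValidationError("need at least one encoder structure")


@dataclass
class TrialRecord:
    trial_id: int
    sampled_config: dict
    objective: float
    status: str  # ok | failed


class RandomSampler:
    """Uniform choice of structure; log-uniform α values."""

    def __init__(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def __call__(self, space: SearchSpace, trial_id: int) -> dict:
        structure = self.rng.choice(list(space.encoder_structures))
        return {
            "structure": str(structure),
            "alpha_z": self._log_uniform(*space.alpha_z_range),
            "alpha_w": self._log_uniform(*space.alpha_w_range),
        }

    def _log_uniform(self, lo: float, hi: float) -> float:
        return float(np.exp(self.rng.uniform(np.log(lo), np.log(hi))))


class GridSampler:
    """Cycle through an explicit list of configurations."""

    def __init__(self, configs: Sequence[dict]):
        self.configs = list(configs)

    def __call__(self, space: SearchSpace, trial_id: int) -> dict:
        return dict(self.configs[trial_id % len(self.configs)])


def run_search(
    space: SearchSpace,
    data,
    base_cfg: Optional[TrainConfig] = None,
    sampler=None,
    preprocess_spec=None,
    covariates=None,
) -> tuple[list[TrialRecord], TrialRecord]:
    """Execute ``space.n_trials`` training trials; return all records and the
    best (argmin objective over trials with status "ok").

    Individual trial failures are recorded, not fatal; the search errors only
    if every trial failed. Deterministic given ``space.seed`` and a
    deterministic sampler.
    """
    space.__post_init__()
    if sampler is None:
        sampler = RandomSampler(space.seed)
    base_cfg = base_cfg or TrainConfig()
    records: list[TrialRecord] = []
    counts = data.values if hasattr(data, "values") else np.asarray(data)
    for trial_id in range(space.n_trials):
        cfg_sample = sampler(space, trial_id)
        record_cfg = dict(cfg_sample)
        record_cfg["max_epochs"] = base_cfg.max_epochs
        try:
            spec = ModelSpec(
                encoder_sizes=parse_structure(cfg_sample["structure"]),
                n_genes=counts.shape[1],
                residuals="full"
                if len(parse_structure(cfg_sample["structure"])) >= 3
                else "none",
                alpha_z=float(cfg_sample["alpha_z"]),
                alpha_w=float(cfg_sample["alpha_w"]),
            )
            model = build_model(spec, seed=space.seed + trial_id)
            result = train(
                model, data, covariates=covariates, cfg=base_cfg,
                preprocess_spec=preprocess_spec,
            )
            records.append(
                TrialRecord(trial_id, record_cfg,
                            float(result.best_validation_loss), "ok")
            )
        except ZipoError as exc:  # pragma: no cover - defensive
            records.append(
                TrialRecord(trial_id, record_cfg | {"error": str(exc)},
                            float("nan"), "failed")
            )
    ok = [r for r in records if r.status == "ok"]
    if not ok:
        raise ZipoError("all hyperparameter trials failed")
    best = min(ok, key=lambda r: r.objective)
    return records, best
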