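"""The zero-inflated count autoencoder network.

Architecture
------------
A deep encoder maps a cell's expression vector to a low-dimensional embedding
``U_c`` through a chain of blocks (dense linear → activation → batch norm).
With residual connections enabled, each interior block output is passed through
a dedicated linear projection to the latent width and the projections are
summed into the latent block's pre-activation — the standard way to bridge
differing widths. Known covariates are concatenated after the encoder,
``V_c = concat(U_c, U'_c)``, and four shallow heads read off ``V_c``:

* library head — a small block stack (default hidden sizes 16 and 4) ending in
  a single linear output, predicting ``log l_c``;
* zero head — one dense linear layer giving per-gene zero-inflation logits
  ``r_cg`` (``z = sigmoid(r)``);
* mean head — one dense linear layer followed by logSoftmax over genes, so the
  normalized means ``μ_cg`` of each cell sum to exactly 1;
* dispersion head (negative binomial only) — one dense linear layer giving
  per-gene log-dispersion ``log θ_cg``.

The expected count for a cell–gene pair is the rate ``m = l·μ``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from ._autodiff import Tensor, concat
from ._layers import ACTIVATIONS, EncoderBlock, Linear
from .data import CovariateTable
from .exceptions import ValidationError

__all__ = [
    "ModelSpec",
    "LatentEmbedding",
    "CellDistribution",
    "middle_layer_size",
    "build_model",
    "forward",
    "export_latents",
    "save_checkpoint",
    "load_checkpoint",
    "ZiPoNetwork",
]


def middle_layer_size(s_first: int, n_latent: int) -> int:
    """Middle-layer width for a 3-layer encoder: the geometric mean of the
    first-layer size and the latent count, rounded to the nearest integer."""
    if s_first < 1 or n_latent < 1:
        raise ValidationError("layer sizes must be >= 1")
    return int(round(np.sqrt(s_first * n_latent)))


@dataclass
class ModelSpec:
    """Full architectural description of the network."""

    encoder_sizes: Sequence[int]
    n_genes: int
    distribution: str = "zip"
    residuals: object = "none"  # "none" | "full" | list of block indices (1-based)
    activation: str = "sigmoid"
    batch_norm: bool = True
    n_covariates: int = 0
    lib_head_sizes: Sequence[int] = (16, 4)
    alpha_z: float = 0.1
    alpha_w: float = 0.1
    alpha_theta: float = 0.0

    def __post_init__(self):
        self.encoder_sizes = [int(s) for s in self.encoder_sizes]
        self.lib_head_sizes = [int(s) for s in self.lib_head_sizes]
        if not self.encoder_sizes or any(s < 1 for s in self.encoder_sizes):
            raise ValidationError("encoder_sizes must be positive integers")
        if self.distribution not in ("zip", "zinb"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")
        if self.activation not in ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_covariates < 0:
            raise ValidationError("n_covariates must be non-negative")
        for a in (self.alpha_z, self.alpha_w, self.alpha_theta):
            if a < 0:
                raise ValidationError("regularization strengths must be >= 0")
        if not all(a > b for a, b in zip(self.encoder_sizes, self.encoder_sizes[1:])):
            warnings.warn("encoder_sizes are not strictly decreasing", stacklevel=2)
        self.residual_sources  # validate

    @property
    def n_latent(self) -> int:
        return self.encoder_sizes[-1]

    @property
    def residual_sources(self) -> list[int]:
        """1-based indices of encoder blocks whose outputs feed residual
        projections into the latent block (interior blocks 2..t-1)."""
        t = len(self.encoder_sizes)
        if self.residuals == "none" or t < 3:
            if isinstance(self.residuals, (list, tuple)) and t < 3:
                raise ValidationError("residual sources require >= 3 encoder blocks")
            return []
        if self.residuals == "full":
            return list(range(2, t))
        if isinstance(self.residuals, (list, tuple)):
            srcs = sorted(int(i) for i in self.residuals)
            if any(i < 2 or i > t - 1 for i in srcs):
                raise ValidationError(
                    f"residual sources must lie in 2..{t - 1}, got {srcs}"
                )
            return srcs
        raise ValidationError(f"unknown residuals setting {self.residuals!r}")

    def to_dict(self) -> dict:
        return {
            "encoder_sizes": list(self.encoder_sizes),
            "n_genes": self.n_genes,
            "distribution": self.distribution,
            "residuals": list(self.residuals)
            if isinstance(self.residuals, (list, tuple))
            else self.residuals,
            "activation": self.activation,
            "batch_norm": self.batch_norm,
            "n_covariates": self.n_covariates,
            "lib_head_sizes": list(self.lib_head_sizes),
            "alpha_z": self.alpha_z,
            "alpha_w": self.alpha_w,
            "alpha_theta": self.alpha_theta,
        }


@dataclass
class LatentEmbedding:
    """Encoder output ``U`` and covariate-augmented representation ``V``."""

    U: np.ndarray
    V: np.ndarray


@dataclass
class CellDistribution:
    """Per-cell predicted distribution parameters.

    ``log_l`` — log library size per cell; ``r`` — zero-inflation logits
    (``z = sigmoid(r)``); ``log_mu`` — per-cell log normalized means (each row
    of ``exp(log_mu)`` sums to 1); ``log_theta`` — log dispersion, negative
    binomial only.
    """

    log_l: np.ndarray
    r: np.ndarray
    log_mu: np.ndarray
    log_theta: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("log_l", "r", "log_mu"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in {name}")
        if self.log_theta is not None and not np.all(np.isfinite(self.log_theta)):
            raise ValidationError("non-finite values in log_theta")
        rows = np.exp(self.log_mu).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValidationError("exp(log_mu) rows must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.r.shape[0]

    @property
    def n_genes(self) -> int:
        return self.r.shape[1]

    def zero_prob(self) -> np.ndarray:
        """Dropout probability z = sigmoid(r)."""
        return expit(self.r)

    def library_size(self) -> np.ndarray:
        return np.exp(self.log_l)

    def mean_rate(self) -> np.ndarray:
        """Expected count m = l·μ."""
        return np.exp(self.log_l[:, None] + self.log_mu)


class ZiPoNetwork:
    """The assembled network; prefer :func:`build_model` for construction."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        sizes = [spec.n_genes] + list(spec.encoder_sizes)
        t = len(spec.encoder_sizes)

        self.encoder_blocks = [
            EncoderBlock(sizes[i], sizes[i + 1], spec.activation, spec.batch_norm, rng)
            for i in range(t)
        ]
        self.residual_projections = {
            src: Linear(spec.encoder_sizes[src - 1], spec.n_latent, rng)
            for src in spec.residual_sources
        }

        v_dim = spec.n_latent + spec.n_covariates
        lib_sizes = [v_dim] + list(spec.lib_head_sizes)
        self.lib_blocks = [
            EncoderBlock(lib_sizes[i], lib_sizes[i + 1], spec.activation,
                         spec.batch_norm, rng)
            for i in range(len(spec.lib_head_sizes))
        ]
        self.lib_out = Linear(lib_sizes[-1], 1, rng)
        self.z_head = Linear(v_dim, spec.n_genes, rng)
        self.mu_head = Linear(v_dim, spec.n_genes, rng)
        self.theta_head = (
            Linear(v_dim, spec.n_genes, rng) if spec.distribution == "zinb" else None
        )

    # -- parameter access -----------------------------------------------------

    def parameters(self):
        ps = []
        for blk in self.encoder_blocks:
            ps += blk.parameters()
        for proj in self.residual_projections.values():
            ps += proj.parameters()
        for blk in self.lib_blocks:
            ps += blk.parameters()
        ps += self.lib_out.parameters()
        ps += self.z_head.parameters()
        ps += self.mu_head.parameters()
        if self.theta_head is not None:
            ps += self.theta_head.parameters()
        return ps

    def first_layer_weights(self) -> np.ndarray:
        """First encoding layer weights as neurons × genes."""
        return self.encoder_blocks[0].linear.W.data.T

    def first_layer_weight_tensor(self):
        return self.encoder_blocks[0].linear.W

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for blk in self.encoder_blocks + self.lib_blocks:
            if blk.bn is not None:
                arrays += [blk.bn.running_mean, blk.bn.running_var]
        return arrays

    # -- forward --------------------------------------------------------------

    def forward_tensors(self, X_input, covariates=None, training: bool = False):
        """Forward pass keeping everything on the autodiff tape.

        Returns ``(U, V, out)`` where ``out`` maps head names to Tensors.
        """
        X_input = np.asarray(X_input, dtype=np.float64)
        if X_input.ndim != 2 or X_input.shape[1] != self.spec.n_genes:
            raise ValidationError(
                f"input has shape {X_input.shape}, expected (*, {self.spec.n_genes})"
            )
        if not np.all(np.isfinite(X_input)):
            raise ValidationError("non-finite values in model input")
        cov_values = None
        if self.spec.n_covariates:
            if covariates is None:
                raise ValidationError(
                    f"model expects {self.spec.n_covariates} covariates"
                )
            cov_values = (
                covariates.values
                if isinstance(covariates, CovariateTable)
                else np.asarray(covariates, dtype=np.float64)
            )
            if cov_values.shape != (X_input.shape[0], self.spec.n_covariates):
                raise ValidationError("covariate shape mismatch")
        elif covariates is not None:
            cov = (
                covariates.values
                if isinstance(covariates, CovariateTable)
                else np.asarray(covariates)
            )
            if cov.size:
                raise ValidationError("model was built without covariates")

        h = Tensor(X_input)
        interior = {}
        for i, blk in enumerate(self.encoder_blocks[:-1], start=1):
            h = blk(h, training)
            if i in self.residual_projections:
                interior[i] = h
        last = self.encoder_blocks[-1]
        pre = last.linear(h)
        for src, proj in self.residual_projections.items():
            pre = pre + proj(interior[src])
        u = ACTIVATIONS[self.spec.activation](pre)
        if last.bn is not None:
            u = last.bn(u, training)

        v = concat([u, Tensor(cov_values)], axis=1) if cov_values is not None else u

        lh = v
        for blk in self.lib_blocks:
            lh = blk(lh, training)
        log_l = self.lib_out(lh).reshape(-1)
        out = {
            "log_l": log_l,
            "r": self.z_head(v),
            "log_mu": self.mu_head(v).log_softmax(axis=1),
        }
        if self.theta_head is not None:
            out["log_theta"] = self.theta_head(v)
        return u, v, out

    def predict(self, X_input, covariates=None, batch_size: int = 256):
        """Evaluation-mode forward over all cells, batched.

        Returns ``(LatentEmbedding, CellDistribution)`` as numpy arrays.
        Batch norm uses running statistics, so the result is independent of the
        batching.
        """
        X_input = np.asarray(X_input, dtype=np.float64)
        n = X_input.shape[0]
        cov_values = None
        if covariates is not None:
            cov_values = (
                covariates.values
                if isinstance(covariates, CovariateTable)
                else np.asarray(covariates, dtype=np.float64)
            )
        chunks = {"U": [], "V": [], "log_l": [], "r": [], "log_mu": [], "log_theta": []}
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            cov_b = cov_values[sl] if cov_values is not None else None
            u, v, out = self.forward_tensors(X_input[sl], cov_b, training=False)
            chunks["U"].append(u.data)
            chunks["V"].append(v.data)
            chunks["log_l"].append(out["log_l"].data)
            chunks["r"].append(out["r"].data)
            chunks["log_mu"].append(out["log_mu"].data)
            if "log_theta" in out:
                chunks["log_theta"].append(out["log_theta"].data)
        emb = LatentEmbedding(
            U=np.concatenate(chunks["U"]), V=np.concatenate(chunks["V"])
        )
        dist = CellDistribution(
            log_l=np.concatenate(chunks["log_l"]),
            r=np.concatenate(chunks["r"]),
            log_mu=np.concatenate(chunks["log_mu"]),
            log_theta=np.concatenate(chunks["log_theta"])
            if chunks["log_theta"]
            else None,
        )
        return emb, dist


def build_model(spec: ModelSpec, seed: int = 0) -> ZiPoNetwork:
    """Construct a network with reproducible seeded initialization."""
    return ZiPoNetwork(spec, seed)


def forward(model: ZiPoNetwork, X_input, covariates=None):
    """Evaluation-mode forward pass (thin wrapper over
    :meth:`ZiPoNetwork.predict`)."""
    return model.predict(X_input, covariates)


def export_latents(embedding: LatentEmbedding, path, cell_ids=None) -> None:
    """Write the latent matrix ``U`` as dense delimited text with cell ids."""
    path = Path(path)
    n, k = embedding.U.shape
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n)]
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.DataFrame(
        embedding.U, index=cell_ids, columns=[f"latent{j}" for j in range(k)]
    )
    df.to_csv(path, sep=sep)


def save_checkpoint(model: ZiPoNetwork, path, extra: dict | None = None) -> None:
    """Save spec, seed, weights and batch-norm state to one ``.npz`` archive."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {"spec": model.spec.to_dict(), "seed": model.seed, "extra": extra or {}}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ZiPoNetwork:
    """Rebuild a network from :func:`save_checkpoint` output."""
    with np.load(path) as arc:
        meta = json.loads(bytes(arc["meta"]).decode())
        spec_d = dict(meta["spec"])
        spec = ModelSpec(**spec_d)
        model = ZiPoNetwork(spec, meta["seed"])
        targets = model.state_arrays()
        for i, target in enumerate(targets):
            target[...] = arc[f"arr_{i}"]
    return model
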