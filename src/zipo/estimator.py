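"""Scikit-learn style estimator wrapping the count autoencoder.

``ZiPoAutoencoder`` is a transformer: ``fit`` trains the network on a cells ×
genes count matrix, ``transform`` returns the latent embedding ``U`` (usable in
sklearn pipelines for clustering or visualization), ``predict`` returns the
denoised rate matrix ``m = l·μ``, and ``score`` the mean zero-inflated
log-likelihood per cell (higher is better).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CountMatrix, PreprocessSpec
from .exceptions import ValidationError
from .losses import zi_log_likelihood
from .model import ModelSpec, build_model
from .training import TrainConfig, impute, train

__all__ = ["ZiPoAutoencoder"]


class ZiPoAutoencoder(BaseEstimator, TransformerMixin):
    """Zero-inflated Poisson / negative-binomial denoising autoencoder.

    Parameters
    ----------
    encoder_sizes : sequence of int
        Encoder layer widths; the last entry is the latent dimension.
    residuals : {"none", "full"} or list of int
        Residual projections from interior encoder blocks into the latent
        block's pre-activation.
    distribution : {"zip", "zinb"}
        Count family: zero-inflated Poisson or negative binomial.
    alpha_z, alpha_w, alpha_theta : float
        Regularization strengths for the zero probabilities, the
        scale-invariant first-layer sparsity term, and the dispersion.
    log_transform, library_normalize : bool
        Optional encoder-input transforms (the likelihood always sees raw
        counts).
    Remaining parameters mirror :class:`~zipo.training.TrainConfig`.
    """

    def __init__(
        self,
        encoder_sizes=(512, 256, 128),
        residuals="full",
        activation="sigmoid",
        batch_norm=True,
        distribution="zip",
        lib_head_sizes=(16, 4),
        alpha_z=0.1,
        alpha_w=0.1,
        alpha_theta=0.0,
        log_transform=False,
        library_normalize=False,
        lr_initial=0.0212,
        lr_target=0.001,
        lr_decay=0.9,
        plateau_patience_epochs=15,
        plateau_min_improvement=0.001,
        plateau_factor=0.5,
        early_stop_epochs=30,
        batch_size=128,
        validation_fraction=0.1,
        max_epochs=500,
        random_state=0,
    ):
        self.encoder_sizes = encoder_sizes
        self.residuals = residuals
        self.activation = activation
        self.batch_norm = batch_norm
        self.distribution = distribution
        self.lib_head_sizes = lib_head_sizes
        self.alpha_z = alpha_z
        self.alpha_w = alpha_w
        self.alpha_theta = alpha_theta
        self.log_transform = log_transform
        self.library_normalize = library_normalize
        self.lr_initial = lr_initial
        self.lr_target = lr_target
        self.lr_decay = lr_decay
        self.plateau_patience_epochs = plateau_patience_epochs
        self.plateau_min_improvement = plateau_min_improvement
        self.plateau_factor = plateau_factor
        self.early_stop_epochs = early_stop_epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.max_epochs = max_epochs
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _preprocess_spec(self) -> PreprocessSpec:
        return PreprocessSpec(
            log_transform=self.log_transform,
            library_normalize=self.library_normalize,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr_initial=self.lr_initial,
            lr_target=self.lr_target,
            lr_decay=self.lr_decay,
            plateau_patience_epochs=self.plateau_patience_epochs,
            plateau_min_improvement=self.plateau_min_improvement,
            plateau_factor=self.plateau_factor,
            early_stop_epochs=self.early_stop_epochs,
            batch_size=self.batch_size,
            validation_fraction=self.validation_fraction,
            max_epochs=self.max_epochs,
            seed=self.random_state,
        )

    @staticmethod
    def _n_covariates(covariates) -> int:
        if covariates is None:
            return 0
        values = getattr(covariates, "values", covariates)
        return np.asarray(values).shape[1]

    def fit(self, X, y=None, covariates=None):
        """Train on a cells × genes count matrix (CountMatrix or array)."""
        counts = X.values if isinstance(X, CountMatrix) else np.asarray(X)
        if counts.ndim != 2:
            raise ValidationError("X must be a 2-D cells × genes count matrix")
        spec = ModelSpec(
            encoder_sizes=list(self.encoder_sizes),
            n_genes=counts.shape[1],
            distribution=self.distribution,
            residuals=self.residuals,
            activation=self.activation,
            batch_norm=self.batch_norm,
            n_covariates=self._n_covariates(covariates),
            lib_head_sizes=list(self.lib_head_sizes),
            alpha_z=self.alpha_z,
            alpha_w=self.alpha_w,
            alpha_theta=self.alpha_theta,
        )
        self.network_ = build_model(spec, seed=self.random_state)
        result = train(
            self.network_,
            X,
            covariates=covariates,
            cfg=self._train_config(),
            preprocess_spec=self._preprocess_spec(),
        )
        self.model_spec_ = spec
        self.n_features_in_ = counts.shape[1]
        self.best_validation_loss_ = result.best_validation_loss
        self.epochs_run_ = result.epochs_run
        self.history_ = result.history
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise ValidationError("estimator is not fitted; call fit first")

    def predict_distribution(self, X, covariates=None):
        """Full per-cell predicted distribution (CellDistribution)."""
        self._check_fitted()
        return impute(
            self.network_, X, covariates=covariates,
            preprocess_spec=self._preprocess_spec(),
        )

    def transform(self, X, covariates=None) -> np.ndarray:
        """Latent embedding ``U`` (cells × latent dimension)."""
        self._check_fitted()
        counts = X.values if isinstance(X, CountMatrix) else np.asarray(X)
        from .data import preprocess

        cm = X if isinstance(X, CountMatrix) else CountMatrix(
            counts,
            [f"cell{i}" for i in range(counts.shape[0])],
            [f"gene{j}" for j in range(counts.shape[1])],
        )
        inputs = preprocess(cm, self._preprocess_spec())
        emb, _ = self.network_.predict(inputs, covariates)
        return emb.U

    def predict(self, X, covariates=None) -> np.ndarray:
        """Denoised expected counts ``m = l·μ``."""
        return self.predict_distribution(X, covariates).mean_rate()

    def score(self, X, y=None, covariates=None) -> float:
        """Mean zero-inflated log-likelihood per cell (higher is better)."""
        dist = self.predict_distribution(X, covariates)
        counts = X.values if isinstance(X, CountMatrix) else np.asarray(X)
        return zi_log_likelihood(counts, dist)
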