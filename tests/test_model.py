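"""Architecture contracts: sizing, residuals, heads, determinism, checkpoints."""

import numpy as np
import pytest
from scipy.special import expit

import zipo
from zipo.exceptions import ValidationError


@pytest.mark.parametrize("s1,latent,expected", [
    (4096, 64, 512),
    (64, 64, 64),
    (2048, 64, 362),
])
def test_middle_layer_geometric_mean(s1, latent, expected):
    assert zipo.middle_layer_size(s1, latent) == expected


def test_full_residuals_project_interior_blocks():
    spec = zipo.ModelSpec(encoder_sizes=[2048, 1024, 512, 256, 128], n_genes=50,
                          residuals="full")
    model = zipo.build_model(spec, seed=0)
    assert sorted(model.residual_projections) == [2, 3, 4]
    widths = [model.residual_projections[i].W.shape[0] for i in (2, 3, 4)]
    assert widths == [1024, 512, 256]
    assert all(p.W.shape[1] == 128 for p in model.residual_projections.values())


def test_zero_head_parameter_count():
    # V of width 10 into 100 genes: 10*100 weights + 100 biases
    spec = zipo.ModelSpec(encoder_sizes=[20, 10], n_genes=100)
    model = zipo.build_model(spec, seed=0)
    n_params = model.z_head.W.data.size + model.z_head.b.data.size
    assert n_params == 10 * 100 + 100


def test_no_residuals_equals_straight_line_composition(rng):
    """Oracle equivalence: an independent numpy reimplementation of the
    sequential eval-mode forward pass on a 4-gene, 2-layer toy model."""
    spec = zipo.ModelSpec(encoder_sizes=[3, 2], n_genes=4, residuals="none")
    model = zipo.build_model(spec, seed=5)
    X = rng.normal(size=(6, 4))

    def block(x, blk):
        h = expit(x @ blk.linear.W.data + blk.linear.b.data)
        h = (h - blk.bn.running_mean) / np.sqrt(blk.bn.running_var + blk.bn.eps)
        return h * blk.bn.gamma.data + blk.bn.beta.data

    h = block(X, model.encoder_blocks[0])
    u_expected = block(h, model.encoder_blocks[1])
    emb, dist = model.predict(X)
    assert np.allclose(emb.U, u_expected, atol=1e-10)
    # heads off V = U
    r_expected = u_expected @ model.z_head.W.data + model.z_head.b.data
    assert np.allclose(dist.r, r_expected, atol=1e-10)
    mu_lin = u_expected @ model.mu_head.W.data + model.mu_head.b.data
    log_mu_expected = mu_lin - np.log(np.exp(mu_lin).sum(1, keepdims=True))
    assert np.allclose(dist.log_mu, log_mu_expected, atol=1e-10)


def test_mean_head_rows_sum_to_one_random_models(rng):
    for k in range(20):
        spec = zipo.ModelSpec(encoder_sizes=[8, 4], n_genes=12,
                              residuals="none", alpha_z=0.0)
        model = zipo.build_model(spec, seed=k)
        X = rng.gamma(2.0, 2.0, size=(5, 12))
        _, dist = model.predict(X)
        assert np.allclose(np.exp(dist.log_mu).sum(axis=1), 1.0, atol=1e-6)


def test_eval_mode_batch_size_invariance(tiny_trained_model):
    model, _, cm = tiny_trained_model
    X = np.log1p(cm.values.astype(float))
    emb_all, dist_all = model.predict(X, batch_size=64)
    emb_one, dist_one = model.predict(X[:1], batch_size=1)
    assert np.allclose(emb_all.U[0], emb_one.U[0], atol=1e-6)
    assert np.allclose(dist_all.r[0], dist_one.r[0], atol=1e-6)
    assert np.allclose(dist_all.log_l[0], dist_one.log_l[0], atol=1e-6)


def test_duplicated_cell_identical_outputs(tiny_trained_model):
    model, _, cm = tiny_trained_model
    X = np.log1p(cm.values[:8].astype(float))
    X2 = np.vstack([X, X[0:1]])
    _, dist = model.predict(X2)
    assert np.array_equal(dist.r[0], dist.r[-1])
    assert np.array_equal(dist.log_mu[0], dist.log_mu[-1])


def test_seeded_build_reproducible():
    spec = zipo.ModelSpec(encoder_sizes=[16, 8], n_genes=20)
    a = zipo.build_model(spec, seed=42)
    b = zipo.build_model(spec, seed=42)
    for pa, pb in zip(a.parameters(), b.parameters()):
        assert np.array_equal(pa.data, pb.data)
    c = zipo.build_model(spec, seed=43)
    assert not np.array_equal(a.parameters()[0].data, c.parameters()[0].data)


def test_covariates_concatenated_after_encoder(rng):
    spec = zipo.ModelSpec(encoder_sizes=[8, 4], n_genes=10, n_covariates=2,
                          residuals="none")
    model = zipo.build_model(spec, seed=0)
    X = rng.normal(size=(5, 10))
    cov = zipo.CovariateTable(rng.normal(size=(5, 2)), ["age", "sex"])
    emb, _ = model.predict(X, covariates=cov)
    assert emb.V.shape == (5, 6)
    assert np.allclose(emb.V[:, :4], emb.U)
    assert np.allclose(emb.V[:, 4:], cov.values)
    with pytest.raises(ValidationError):
        model.predict(X)  # covariates required


def test_shape_and_finiteness_validation(rng):
    spec = zipo.ModelSpec(encoder_sizes=[8, 4], n_genes=10)
    model = zipo.build_model(spec, seed=0)
    with pytest.raises(ValidationError, match="shape"):
        model.forward_tensors(rng.normal(size=(3, 7)))
    bad = rng.normal(size=(3, 10))
    bad[1, 2] = np.nan
    with pytest.raises(ValidationError, match="non-finite"):
        model.forward_tensors(bad)


def test_nondecreasing_sizes_warn_not_error():
    with pytest.warns(UserWarning, match="strictly decreasing"):
        zipo.ModelSpec(encoder_sizes=[64, 64], n_genes=10)


def test_invalid_residual_subset_rejected():
    with pytest.raises(ValidationError, match="residual sources"):
        zipo.ModelSpec(encoder_sizes=[16, 8, 4], n_genes=10, residuals=[3])


def test_export_latents_round_trip(tmp_path, rng):
    import pandas as pd

    emb = zipo.LatentEmbedding(U=rng.normal(size=(2, 3)), V=rng.normal(size=(2, 3)))
    path = tmp_path / "latents.tsv"
    zipo.export_latents(emb, path, cell_ids=["c1", "c2"])
    df = pd.read_csv(path, sep="\t", index_col=0)
    assert df.shape == (2, 3)
    assert np.allclose(df.to_numpy(), emb.U)


def test_checkpoint_round_trip(tmp_path, tiny_trained_model):
    model, _, cm = tiny_trained_model
    X = np.log1p(cm.values.astype(float))
    path = tmp_path / "ckpt.npz"
    zipo.save_checkpoint(model, path)
    restored = zipo.load_checkpoint(path)
    _, d0 = model.predict(X)
    _, d1 = restored.predict(X)
    assert np.array_equal(d0.r, d1.r)
    assert np.array_equal(d0.log_mu, d1.log_mu)
    assert np.array_equal(d0.log_l, d1.log_l)
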