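"""Likelihood and penalty correctness against independent oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import zipo
from zipo._autodiff import Tensor
from zipo.exceptions import NumericError, ValidationError
from zipo.losses import total_loss_t, zi_log_likelihood_t


def naive_mixture_loglik(x, r, log_m, log_theta=None, dtype=np.longdouble):
    """Brute-force mixture log(z·1[x=0] + (1−z)·pmf) in extended precision."""
    x = np.asarray(x, dtype=dtype)
    z = 1.0 / (1.0 + np.exp(-np.asarray(r, dtype=dtype)))
    m = np.exp(np.asarray(log_m, dtype=dtype))
    if log_theta is None:
        from scipy.special import gammaln

        logf = x * np.log(m) - m - gammaln(np.asarray(x, float) + 1.0).astype(dtype)
    else:
        from scipy.special import gammaln

        theta = np.exp(np.asarray(log_theta, dtype=dtype))
        xf = np.asarray(x, float)
        logf = (
            gammaln(xf + np.asarray(np.exp(log_theta), float)).astype(dtype)
            - gammaln(np.asarray(np.exp(log_theta), float)).astype(dtype)
            - gammaln(xf + 1.0).astype(dtype)
            + theta * np.log(theta / (theta + m))
            + x * np.log(m / (theta + m))
        )
    mix = (x == 0) * z + (1 - z) * np.exp(logf)
    return np.log(mix)


@pytest.mark.parametrize("x,m,expected", [
    (0, 1.0, -1.0),
    (1, 1.0, -1.0),
    (3, 2.5, None),  # checked against scipy below
])
def test_poisson_log_pmf(x, m, expected):
    got = zipo.poisson_log_pmf(x, np.log(m))
    oracle = stats.poisson.logpmf(x, m)
    assert np.isclose(got, oracle, atol=1e-12)
    if expected is not None:
        assert np.isclose(got, expected, atol=1e-12)


def test_poisson_rejects_non_integer():
    with pytest.raises(ValidationError):
        zipo.poisson_log_pmf(1.5, 0.0)


def test_nb_log_pmf_against_scipy(rng):
    for _ in range(50):
        x = rng.integers(0, 20)
        m = float(np.exp(rng.normal(0, 2)))
        theta = float(np.exp(rng.normal(0, 2)))
        got = zipo.nb_log_pmf(x, np.log(m), np.log(theta))
        oracle = stats.nbinom.logpmf(x, theta, theta / (theta + m))
        assert np.isclose(got, oracle, rtol=1e-10, atol=1e-10)


def test_nb_closed_forms():
    m, theta = 2.0, 3.0
    assert np.isclose(
        zipo.nb_log_pmf(0, np.log(m), np.log(theta)),
        theta * np.log(theta / (theta + m)),
    )
    # theta = 1 is geometric with success probability 1/2 at m = 1
    assert np.isclose(zipo.nb_log_pmf(2, 0.0, 0.0), np.log(1 / 8))


def test_nb_poisson_limit():
    rng = np.random.default_rng(1)
    for _ in range(20):
        x = rng.integers(0, 15)
        log_m = rng.normal(0, 1.5)
        assert np.isclose(
            zipo.nb_log_pmf(x, log_m, 20.0),
            zipo.poisson_log_pmf(x, log_m),
            atol=1e-4,
        )


def _dist(log_l, r, log_mu, log_theta=None):
    return zipo.CellDistribution(
        log_l=np.asarray(log_l, float),
        r=np.asarray(r, float),
        log_mu=np.asarray(log_mu, float),
        log_theta=None if log_theta is None else np.asarray(log_theta, float),
    )


def test_zi_loglik_no_inflation_limit(rng):
    x = rng.poisson(2.0, size=(4, 6))
    log_mu = np.log(rng.dirichlet(np.ones(6), size=4))
    log_l = rng.normal(1.0, 0.5, 4)
    dist = _dist(log_l, np.full((4, 6), -40.0), log_mu)
    got = zipo.zi_log_likelihood(x, dist)
    plain = zipo.poisson_log_pmf(x, log_l[:, None] + log_mu).sum() / 4
    assert np.isclose(got, plain, atol=1e-10)


def test_zi_loglik_single_zero_entry_mixture_value():
    # z = 0.5, x = 0, m = 1: log(0.5 + 0.5/e)
    dist = _dist([0.0], [[0.0]], [[0.0]])
    got = zipo.zi_log_likelihood(np.array([[0]]), dist)
    assert np.isclose(got, np.log(0.5 + 0.5 * np.exp(-1.0)), atol=1e-12)


@pytest.mark.parametrize("family", ["zip", "zinb"])
def test_zi_loglik_matches_naive_mixture(rng, family):
    n, g = 6, 5
    x = rng.poisson(1.5, size=(n, g))
    r = rng.uniform(-3, 3, size=(n, g))
    log_mu = np.log(rng.dirichlet(np.ones(g), size=n))
    log_l = rng.normal(1.0, 1.0, n)
    log_theta = rng.normal(0, 1, size=(n, g)) if family == "zinb" else None
    dist = _dist(log_l, r, log_mu, log_theta)
    got = zipo.zi_log_likelihood(x, dist)
    log_m = log_l[:, None] + log_mu
    naive = float(naive_mixture_loglik(x, r, log_m, log_theta).sum() / n)
    assert np.isclose(got, naive, atol=1e-8)


def test_stable_form_finite_where_naive_underflows():
    # positive count with an extreme rate: naive float64 mixture underflows
    x = np.array([[3]])
    log_mu = np.array([[0.0]])
    dist = _dist([8.0], [[-5.0]], log_mu)  # m = e^8, f(3; m) ~ -2980
    with np.errstate(divide="ignore"):
        naive64 = np.log(
            (1 - expit(-5.0)) * np.exp(zipo.poisson_log_pmf(3, 8.0))
        )
    assert np.isinf(naive64)
    got = zipo.zi_log_likelihood(x, dist)
    assert np.isfinite(got)


# -- scale-invariant weight penalty --------------------------------------------


def test_weight_penalty_constant_rows_is_one():
    assert np.isclose(zipo.scale_invariant_weight_penalty(np.full((5, 30), 0.7)), 1.0)


def test_weight_penalty_one_hot_rows():
    W = np.zeros((4, 100))
    W[np.arange(4), [3, 10, 50, 99]] = [2.0, -1.0, 0.5, 7.0]
    assert np.isclose(zipo.scale_invariant_weight_penalty(W), 0.1)


def test_weight_penalty_scale_invariance(rng):
    W = rng.normal(size=(6, 40))
    before = zipo.scale_invariant_weight_penalty(W)
    W2 = W.copy()
    W2[3] *= 1e6
    after = zipo.scale_invariant_weight_penalty(W2)
    assert abs(after - before) / before < 1e-12


def test_weight_penalty_bounds_and_sparsity_direction(rng):
    W = rng.normal(size=(8, 25))
    mean_abs = np.abs(W).mean(axis=1)
    rms = np.sqrt((W ** 2).mean(axis=1))
    terms = mean_abs / rms
    assert np.all(terms >= 1 / np.sqrt(25) - 1e-12)
    assert np.all(terms <= 1 + 1e-12)
    # appending zero columns lowers each row term (rewards sparsity)
    W_padded = np.hstack([W, np.zeros((8, 25))])
    assert (zipo.scale_invariant_weight_penalty(W_padded)
            < zipo.scale_invariant_weight_penalty(W))


def test_weight_penalty_zero_row_contributes_zero():
    W = np.zeros((2, 10))
    W[0] = 1.0
    with pytest.warns(UserWarning, match="all-zero"):
        val = zipo.scale_invariant_weight_penalty(W)
    assert np.isclose(val, 0.5)  # (1 + 0) / 2


# -- total loss ----------------------------------------------------------------


def test_total_loss_zip_reduces_to_nll(rng):
    x = rng.poisson(1.0, size=(3, 4))
    log_mu = np.log(rng.dirichlet(np.ones(4), size=3))
    dist = _dist(rng.normal(0, 1, 3), rng.uniform(-2, 2, (3, 4)), log_mu)
    spec = zipo.ModelSpec(encoder_sizes=[4, 2], n_genes=4, alpha_z=0.0,
                          alpha_w=0.0)
    bd = zipo.total_loss(x, dist, rng.normal(size=(2, 4)), spec)
    assert bd.total == bd.nll
    assert bd.zero_penalty == bd.weight_penalty == bd.rate_penalty == 0.0


def test_total_loss_hand_computed_case():
    """Term-by-term evaluation of a fixed 2-cell, 3-gene ZIP instance."""
    x = np.array([[0, 2, 1], [3, 0, 0]])
    log_l = np.array([np.log(4.0), np.log(6.0)])
    mu = np.array([[0.5, 0.25, 0.25], [0.2, 0.3, 0.5]])
    r = np.array([[0.0, -1.0, 1.0], [0.5, -0.5, 2.0]])
    dist = _dist(log_l, r, np.log(mu))
    W = np.array([[1.0, -2.0, 0.5], [0.0, 3.0, 1.0]])
    spec = zipo.ModelSpec(encoder_sizes=[3, 2], n_genes=3, alpha_z=0.7,
                          alpha_w=1.3)

    m = np.exp(log_l)[:, None] * mu
    z = expit(r)
    from scipy.special import gammaln

    mix = np.where(
        x == 0, z + (1 - z) * np.exp(-m),
        (1 - z) * np.exp(x * np.log(m) - m - gammaln(x + 1.0)),
    )
    nll_expected = -np.log(mix).sum() / 2
    zero_expected = 0.7 * (z ** 2).mean()
    terms = np.abs(W).mean(axis=1) / np.sqrt((W ** 2).mean(axis=1))
    weight_expected = 1.3 * terms.mean()

    bd = zipo.total_loss(x, dist, W, spec)
    assert np.isclose(bd.nll, nll_expected, atol=1e-9)
    assert np.isclose(bd.zero_penalty, zero_expected, atol=1e-12)
    assert np.isclose(bd.weight_penalty, weight_expected, atol=1e-12)
    assert np.isclose(bd.total,
                      nll_expected + zero_expected + weight_expected, atol=1e-9)


def test_zinb_rate_penalty_definition(rng):
    x = rng.poisson(2.0, size=(3, 4))
    log_mu = np.log(rng.dirichlet(np.ones(4), size=3))
    log_l = rng.normal(1, 0.5, 3)
    dist = _dist(log_l, rng.uniform(-1, 1, (3, 4)), log_mu,
                 log_theta=np.zeros((3, 4)))
    spec = zipo.ModelSpec(encoder_sizes=[4, 2], n_genes=4, distribution="zinb",
                          alpha_z=0.0, alpha_w=0.0, alpha_theta=0.5)
    bd = zipo.total_loss(x, dist, rng.normal(size=(2, 4)), spec)
    lib = x.sum(axis=1)
    assert np.isclose(bd.rate_penalty,
                      0.1 * ((np.exp(log_l) - lib) ** 2).mean(), atol=1e-9)
    assert np.isclose(bd.theta_penalty, 0.5 * 1.0, atol=1e-12)  # theta = 1


def test_zinb_total_nll_matches_zip_in_poisson_limit(rng):
    x = rng.poisson(1.5, size=(5, 6))
    log_mu = np.log(rng.dirichlet(np.ones(6), size=5))
    log_l = rng.normal(1, 0.5, 5)
    r = rng.uniform(-2, 2, (5, 6))
    zip_dist = _dist(log_l, r, log_mu)
    zinb_dist = _dist(log_l, r, log_mu, log_theta=np.full((5, 6), 20.0))
    assert np.isclose(
        zipo.zi_log_likelihood(x, zinb_dist),
        zipo.zi_log_likelihood(x, zip_dist),
        atol=1e-3,
    )


def test_tape_loss_matches_numpy_loss(rng):
    """The training-tape loss and the reporting loss agree term by term."""
    n, g = 5, 7
    x = rng.poisson(1.0, size=(n, g))
    log_mu = np.log(rng.dirichlet(np.ones(g), size=n))
    log_l = rng.normal(0.5, 0.5, n)
    r = rng.uniform(-2, 2, (n, g))
    spec = zipo.ModelSpec(encoder_sizes=[6, 3], n_genes=g, alpha_z=0.3,
                          alpha_w=0.9)
    W_rows = rng.normal(size=(3, g))  # neurons x genes
    dist = _dist(log_l, r, log_mu)
    bd_np = zipo.total_loss(x, dist, W_rows, spec)
    out = {"log_l": Tensor(log_l), "r": Tensor(r), "log_mu": Tensor(log_mu)}
    total_t, bd_t = total_loss_t(x, out, Tensor(W_rows.T), spec)
    assert np.isclose(bd_t.nll, bd_np.nll, atol=1e-9)
    assert np.isclose(bd_t.zero_penalty, bd_np.zero_penalty, atol=1e-12)
    assert np.isclose(bd_t.weight_penalty, bd_np.weight_penalty, atol=1e-9)
    assert np.isclose(total_t.item(), bd_np.total, atol=1e-9)


def test_loss_breakdown_validation():
    bd = zipo.LossBreakdown(np.nan, 0, 0, 0, 0)
    with pytest.raises(NumericError, match="nll"):
        bd.validate()


def test_perfect_rates_do_not_increase_positive_term(rng):
    """Replacing the rates with the observed positive counts can only improve
    the positive-entry Poisson term."""
    x = rng.poisson(3.0, size=(4, 5)) + 1
    log_mu = np.log(rng.dirichlet(np.ones(5), size=4))
    log_l = rng.normal(1, 1, 4)
    log_m = log_l[:, None] + log_mu
    imperfect = zipo.poisson_log_pmf(x, log_m).sum()
    perfect = zipo.poisson_log_pmf(x, np.log(x)).sum()
    assert perfect >= imperfect
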