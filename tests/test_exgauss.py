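"""Ex-Gaussian density, moments and sampler against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import emosearch as es
from emosearch.exgauss import ExGaussianParams, exgauss_logpdf


def convolution_pdf(t, mu, sigma, tau):
    """Numerical-quadrature oracle: density of Normal(mu, sigma) + Exp(tau),
    integrating the Gaussian against the exponential kernel."""

    def integrand(x):
        return stats.norm.pdf(x, mu, sigma) * np.exp(-(t - x) / tau) / tau

    lo = mu - 12 * sigma
    hi = min(t, mu + 12 * sigma)
    if hi <= lo:
        return 0.0
    pts = [p for p in (mu - 2 * sigma, mu, mu + 2 * sigma) if lo < p < hi]
    val, _ = integrate.quad(integrand, lo, hi, limit=300, points=pts or None)
    return val


GRID_PARAMS = [
    (0.0, 1.0, 1.0),
    (3.21, 0.98, 1.52),
    (1.58, 0.51, 0.57),
    (2.0, 0.3, 0.05),
    (0.5, 0.05, 2.0),
]


@pytest.mark.parametrize("mu,sigma,tau", GRID_PARAMS)
def test_pdf_matches_numerical_convolution(mu, sigma, tau):
    ts = mu + tau + np.array([-2.5, -1.0, -0.3, 0.0, 0.4, 1.5, 4.0]) * np.sqrt(
        sigma**2 + tau**2
    )
    for t in ts:
        expected = convolution_pdf(t, mu, sigma, tau)
        got = float(es.exgauss_pdf(t, mu=mu, sigma=sigma, tau=tau))
        assert got == pytest.approx(expected, abs=1e-9)


def test_pdf_reference_value():
    # frozen from the quadrature oracle at (t=0; mu=0, sigma=1, tau=1)
    assert float(es.exgauss_pdf(0.0, mu=0, sigma=1, tau=1)) == pytest.approx(
        0.2615782918651232, abs=1e-9
    )


def test_pdf_agrees_with_scipy_exponnorm():
    ts = np.linspace(-4, 15, 97)
    for mu, sigma, tau in GRID_PARAMS:
        ref = stats.exponnorm(K=tau / sigma, loc=mu, scale=sigma).pdf(ts)
        got = es.exgauss_pdf(ts, mu=mu, sigma=sigma, tau=tau)
        np.testing.assert_allclose(got, ref, atol=1e-10)


@pytest.mark.parametrize("mu,sigma,tau", GRID_PARAMS)
def test_pdf_integrates_to_one(mu, sigma, tau):
    total, _ = integrate.quad(
        lambda t: float(es.exgauss_pdf(t, mu=mu, sigma=sigma, tau=tau)),
        mu - 10 * sigma,
        mu + tau + 30 * max(sigma, tau),
        limit=300,
    )
    assert total == pytest.approx(1.0, abs=1e-6)


def test_small_tau_limit_collapses_to_gaussian():
    peak = float(es.exgauss_pdf(0.0, mu=0.0, sigma=1.0, tau=1e-6))
    assert peak == pytest.approx(1.0 / np.sqrt(2 * np.pi), rel=1e-4)


def test_moments_closed_form():
    p = ExGaussianParams(1.58, 0.51, 0.57)
    mean, var = es.exgauss_moments(p)
    assert mean == pytest.approx(2.15)
    assert var == pytest.approx(0.51**2 + 0.57**2)


def test_sampler_moments_match_closed_form():
    p = ExGaussianParams(3.21, 0.98, 1.52)
    n = 1_000_000
    x = es.sample_exgauss(n, p, rng=7)
    mean, var = es.exgauss_moments(p)
    se_mean = np.sqrt(var / n)
    assert abs(x.mean() - mean) < 3 * se_mean
    # SE of the sample variance via the fourth central moment
    m4 = np.mean((x - x.mean()) ** 4)
    se_var = np.sqrt((m4 - var**2) / n)
    assert abs(x.var() - var) < 3 * se_var


def test_sampler_deterministic_given_seed():
    p = ExGaussianParams(1.0, 0.2, 0.3)
    a = es.sample_exgauss(1000, p, rng=3)
    b = es.sample_exgauss(1000, p, rng=3)
    np.testing.assert_array_equal(a, b)


def test_sampler_skewness_approaches_exponential_limit():
    p = ExGaussianParams(0.0, 0.01, 1.0)
    x = es.sample_exgauss(400_000, p, rng=11)
    skew = float(stats.skew(x))
    assert skew == pytest.approx(2.0, abs=0.05)


def test_positive_only_rejection():
    p = ExGaussianParams(0.05, 0.5, 0.1)  # frequent negative raw draws
    x = es.sample_exgauss(20_000, p, rng=5, positive_only=True)
    assert np.all(x > 0)


@pytest.mark.parametrize("bad", [dict(mu=1, sigma=0, tau=1), dict(mu=1, sigma=1, tau=-2)])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ValueError):
        ExGaussianParams(**bad)
    with pytest.raises(ValueError):
        es.exgauss_pdf(1.0, **bad)


def test_sample_requires_positive_n():
    with pytest.raises(ValueError):
        es.sample_exgauss(0, ExGaussianParams(1, 1, 1))


@settings(max_examples=60, deadline=None)
@given(
    t=st.floats(-50, 50),
    mu=st.floats(-5, 5),
    sigma=st.floats(0.01, 5),
    tau=st.floats(0.01, 5),
)
def test_logpdf_always_finite_and_pdf_nonnegative(t, mu, sigma, tau):
    lp = float(exgauss_logpdf(t, mu, sigma, tau))
    assert np.isfinite(lp)
    assert np.exp(lp) >= 0.0
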