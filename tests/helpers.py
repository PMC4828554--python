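"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here deliberately avoids the package's own samplers: posterior
quantities are computed by dense grid integration of the joint density, and
distributional constants by quadrature, so agreement with the MCMC output is
a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats

from bsfareg.betareg import BetaRegPriors
from bsfareg.sfa import FrontierPriors


def composed_error_logpdf(eps, sigma2, lam):
    """Log density of v - u for v ~ N(0, sigma2) and half-normal u (var lam)."""
    s = np.sqrt(sigma2 + lam)
    return (
        np.log(2.0)
        + stats.norm.logpdf(eps / s)
        - np.log(s)
        + stats.norm.logcdf(-eps * np.sqrt(lam / sigma2) / s)
    )


def frontier_grid_posterior(
    y: np.ndarray,
    x: np.ndarray,
    priors: FrontierPriors,
    beta_grid: np.ndarray,
    log_sigma2_grid: np.ndarray,
    log_lambda_grid: np.ndarray,
):
    """Marginal posterior mean/sd of a scalar frontier coefficient.

    Dense 3-D grid over (beta, log sigma2, log lambda) with the latent
    inefficiencies integrated out analytically through the composed-error
    density.  Returns (mean, sd, edge_mass) where edge_mass is the largest
    probability mass on any grid face (should be tiny if the grid covers
    the posterior).
    """
    B, S, L = np.meshgrid(
        beta_grid, np.exp(log_sigma2_grid), np.exp(log_lambda_grid), indexing="ij"
    )
    lp = np.zeros_like(B)
    for yi, xi in zip(y, x):
        lp += composed_error_logpdf(yi - xi * B, S, L)
    lp += stats.norm.logpdf(B, 0.0, priors.beta_prior_sd)
    lp += stats.invgamma.logpdf(S, priors.noise_precision_shape, scale=priors.noise_precision_rate)
    lp += stats.invgamma.logpdf(L, priors.ineff_precision_shape, scale=priors.ineff_precision_rate)
    lp += np.log(S) + np.log(L)  # Jacobian of the log-scale grid
    w = np.exp(lp - lp.max())
    w /= w.sum()
    mean = float((w * B).sum())
    sd = float(np.sqrt((w * (B - mean) ** 2).sum()))
    edge = max(
        w[0].sum(), w[-1].sum(), w[:, 0].sum(), w[:, -1].sum(), w[:, :, 0].sum(), w[:, :, -1].sum()
    )
    return mean, sd, float(edge)


def betareg_grid_posterior(
    y: np.ndarray,
    priors: BetaRegPriors,
    beta_grid: np.ndarray,
    log_phi_grid: np.ndarray,
):
    """Intercept-only beta-regression posterior moments by 2-D grid.

    Returns ((mean_b0, sd_b0), (mean_phi, sd_phi), edge_mass).
    """
    B, F = np.meshgrid(beta_grid, np.exp(log_phi_grid), indexing="ij")
    mu = special.expit(B)
    lp = np.zeros_like(B)
    for yi in y:
        lp += (
            special.gammaln(F)
            - special.gammaln(mu * F)
            - special.gammaln((1.0 - mu) * F)
            + (mu * F - 1.0) * np.log(yi)
            + ((1.0 - mu) * F - 1.0) * np.log1p(-yi)
        )
    lp += stats.norm.logpdf(B, 0.0, priors.beta_prior_sd)
    lp += stats.gamma.logpdf(F, priors.phi_prior_shape, scale=1.0 / priors.phi_prior_rate)
    lp += np.log(F)
    w = np.exp(lp - lp.max())
    w /= w.sum()

    def moments(A):
        m = float((w * A).sum())
        return m, float(np.sqrt((w * (A - m) ** 2).sum()))

    edge = max(w[0].sum(), w[-1].sum(), w[:, 0].sum(), w[:, -1].sum())
    return moments(B), moments(F), float(edge)


def halfnormal_exp_neg_mean_quadrature(lam: float) -> float:
    """E[exp(-u)] for half-normal u (underlying variance lam), by quadrature."""
    sd = np.sqrt(lam)

    def integrand(u):
        return np.exp(-u) * 2.0 * stats.norm.pdf(u, scale=sd)

    val, err = integrate.quad(integrand, 0.0, 40.0 * sd)
    assert err < 1e-8
    return val


def truncnorm_nonneg_moments_quadrature(r: float, sigma2: float, lam: float):
    """Mean/variance of u >= 0 with density prop. to the augmented kernel.

    Integrates exp(-(u - r)^2 / (2 sigma2)) * exp(-u^2 / (2 lam)) directly,
    independent of the completed-square form used by the implementation.
    """

    def kernel(u):
        return np.exp(-((u - r) ** 2) / (2.0 * sigma2) - u**2 / (2.0 * lam))

    z, _ = integrate.quad(kernel, 0.0, np.inf)
    m1, _ = integrate.quad(lambda u: u * kernel(u), 0.0, np.inf)
    m2, _ = integrate.quad(lambda u: u * u * kernel(u), 0.0, np.inf)
    mean = m1 / z
    return mean, m2 / z - mean**2


def quantile_sort_oracle(chain: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile computed from first principles."""
    s = np.sort(np.asarray(chain, dtype=float))
    h = (s.shape[0] - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, s.shape[0] - 1)
    return float(s[lo] + (h - lo) * (s[hi] - s[lo]))
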