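"""Beta regression with a logit link.

The response ``y`` lives strictly inside (0, 1) and is beta-distributed with
mean/precision parameterization: density

    f(y; mu, phi) = G(phi) / (G(mu phi) G((1-mu) phi))
                    * y^(mu phi - 1) * (1-y)^((1-mu) phi - 1)

so E[y] = mu and Var[y] = mu(1-mu)/(1+phi).  The mean follows
``logit(mu_t) = x_t' beta`` with a constant precision ``phi``.

Two fitting routes are provided and tested against each other: a
Newton-polished maximum-likelihood fit (:func:`fit_ml`) and an adaptive
random-walk Metropolis sampler (:func:`run_beta_mcmc`) with Normal priors on
``beta`` and a Gamma prior on ``phi``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from bsfareg.sfa import McmcSettings

__all__ = [
    "BetaRegData",
    "BetaRegPriors",
    "BetaRegDraws",
    "BetaRegFit",
    "logit",
    "inv_logit",
    "beta_logpdf",
    "loglik",
    "fit_ml",
    "run_beta_mcmc",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BetaRegData:
    """Cross-section of (0,1) responses with an intercept-led design table."""

    units: np.ndarray
    y: np.ndarray
    X: np.ndarray
    x_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.units.shape[0] != self.y.shape[0] or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("units, y and X must have equal length")
        if not np.isfinite(self.X).all():
            raise ValueError("design contains non-finite values")
        if ((self.y <= 0) | (self.y >= 1)).any() or not np.isfinite(self.y).all():
            bad = self.units[(self.y <= 0) | (self.y >= 1) | ~np.isfinite(self.y)]
            raise ValueError(f"responses must lie strictly in (0, 1); offending units: {list(bad)}")
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("design needs at least an intercept column")
        if not self.x_names:
            self.x_names = [f"X{j}" for j in range(1, self.X.shape[1])]
        if len(self.x_names) != self.X.shape[1] - 1:
            raise ValueError("x_names must name the non-intercept columns")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def coef_names(self) -> list[str]:
        return ["const", *self.x_names]

    def to_frame(self) -> pd.DataFrame:
        cols = {"unit": self.units, "score": self.y}
        for j, name in enumerate(self.x_names, start=1):
            cols[name] = self.X[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaRegData":
        required = {"unit", "score"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"indicator CSV missing columns: {sorted(missing)}")
        x_names = [c for c in frame.columns if c not in required]
        n = len(frame)
        X = np.column_stack([np.ones(n)] + [frame[c].to_numpy(dtype=float) for c in x_names])
        return cls(
            units=frame["unit"].to_numpy(dtype=object),
            y=frame["score"].to_numpy(dtype=float),
            X=X,
            x_names=list(x_names),
        )

    @classmethod
    def read_csv(cls, path) -> "BetaRegData":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class BetaRegPriors:
    beta_prior_sd: float = 100.0
    phi_prior_shape: float = 0.01
    phi_prior_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("beta_prior_sd", "phi_prior_shape", "phi_prior_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class BetaRegDraws:
    beta_draws: np.ndarray  # (draws, 1+p)
    phi_draws: np.ndarray  # (draws,)
    accept_rate_beta: float
    accept_rate_phi: float
    coef_names: list[str]

    def __post_init__(self) -> None:
        if (self.phi_draws <= 0).any():
            raise ValueError("phi draws must be strictly positive")

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    def params_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.beta_draws, columns=self.coef_names)
        frame["phi"] = self.phi_draws
        return frame


@dataclass
class BetaRegFit:
    """Maximum-likelihood estimate with observed-information standard errors."""

    beta: np.ndarray
    phi: float
    se_beta: np.ndarray
    se_phi: float
    loglik: float
    grad_norm: float
    n_iter: int


# ---------------------------------------------------------------------------
# link and likelihood
# ---------------------------------------------------------------------------


def logit(mu):
    """Log-odds of ``mu``; requires 0 < mu < 1 elementwise."""
    arr = np.asarray(mu, dtype=float)
    if ((arr <= 0) | (arr >= 1)).any():
        raise ValueError("logit requires arguments strictly inside (0, 1)")
    out = np.log(arr) - np.log1p(-arr)
    return float(out) if np.isscalar(mu) else out


def inv_logit(eta):
    """Numerically stable inverse logit (logistic function)."""
    out = special.expit(np.asarray(eta, dtype=float))
    return float(out) if np.isscalar(eta) else out


def beta_logpdf(y, mu, phi):
    """Log density of the mean/precision beta distribution (vectorized)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if (phi <= 0).any():
        raise ValueError("phi must be strictly positive")
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError("y must lie strictly inside (0, 1)")
    if ((mu <= 0) | (mu >= 1)).any():
        raise ValueError("mu must lie strictly inside (0, 1)")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return float(out) if out.ndim == 0 else out


def _loglik_arrays(y: np.ndarray, X: np.ndarray, beta: np.ndarray, phi: float) -> float:
    eta = X @ beta
    mu = special.expit(eta)
    # mu hitting 0/1 by overflow makes the likelihood -inf rather than an error
    if ((mu <= 0) | (mu >= 1)).any():
        return -np.inf
    return float(np.sum(beta_logpdf(y, mu, phi)))


def loglik(data: BetaRegData, beta: np.ndarray, phi: float) -> float:
    """Sum of :func:`beta_logpdf` over observations at logit-linear means."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != data.n_coef:
        raise ValueError(f"expected {data.n_coef} coefficients, got {beta.shape[0]}")
    if phi <= 0:
        raise ValueError("phi must be strictly positive")
    return _loglik_arrays(data.y, data.X, beta, phi)


def _score(y: np.ndarray, X: np.ndarray, beta: np.ndarray, phi: float) -> np.ndarray:
    """Analytic gradient of the log-likelihood in (beta, phi)."""
    mu = special.expit(X @ beta)
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
    g_beta = phi * (X.T @ ((ystar - mustar) * mu * (1.0 - mu)))
    g_phi = np.sum(
        special.digamma(phi)
        - mu * special.digamma(mu * phi)
        - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
        + mu * np.log(y)
        + (1.0 - mu) * np.log1p(-y)
    )
    return np.append(g_beta, g_phi)


def _num_hessian(y, X, theta, eps=1e-5) -> np.ndarray:
    """Central finite differences of the analytic score in (beta, phi)."""
    k = theta.shape[0]
    H = np.empty((k, k))
    for j in range(k):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += step
        tm[j] -= step
        gp = _score(y, X, tp[:-1], tp[-1])
        gm = _score(y, X, tm[:-1], tm[-1])
        H[:, j] = (gp - gm) / (2.0 * step)
    return (H + H.T) / 2.0


def fit_ml(data: BetaRegData, max_iter: int = 200, tol: float = 1e-8) -> BetaRegFit:
    """Maximum-likelihood fit by quasi-Newton start plus Newton polish.

    Starts from an OLS regression of the empirical logits, runs BFGS on
    (beta, log phi) with the analytic gradient, then Newton steps on
    (beta, phi) until the gradient norm drops below ``tol``.  Standard
    errors come from the inverse observed information.
    """
    y, X = data.y, data.X
    k = data.n_coef
    if data.n_obs <= k + 1:
        raise ValueError("need more observations than parameters plus one")

    z = logit(y)
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    mu0 = special.expit(X @ beta0)
    resid_var = max(float(np.var(z - X @ beta0)), 1e-6)
    # moment start: Var(y) ~ mu(1-mu)/(1+phi) via delta method on the logit scale
    phi0 = max(float(np.mean(1.0 / (resid_var * mu0 * (1.0 - mu0)))) - 1.0, 1.0)

    def negloglik_logphi(params):
        beta, logphi = params[:-1], params[-1]
        return -_loglik_arrays(y, X, beta, np.exp(logphi))

    def neggrad_logphi(params):
        beta, logphi = params[:-1], params[-1]
        phi = np.exp(logphi)
        g = _score(y, X, beta, phi)
        g[-1] *= phi  # chain rule for log phi
        return -g

    start = np.append(beta0, np.log(phi0))
    res = optimize.minimize(
        negloglik_logphi, start, jac=neggrad_logphi, method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-9},
    )
    theta = np.append(res.x[:-1], np.exp(res.x[-1]))

    # Newton polish in (beta, phi) until the stationarity contract holds
    n_newton = 0
    for n_newton in range(1, 51):
        g = _score(y, X, theta[:-1], theta[-1])
        if np.linalg.norm(g) < tol:
            break
        H = _num_hessian(y, X, theta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular observed information during polish: {exc}") from exc
        cand = theta - step
        scale = 1.0
        while cand[-1] <= 0 or not np.isfinite(
            _loglik_arrays(y, X, cand[:-1], cand[-1])
        ):
            scale /= 2.0
            if scale < 1e-8:
                raise RuntimeError("Newton polish failed to find an admissible step")
            cand = theta - scale * step
        theta = cand
    g = _score(y, X, theta[:-1], theta[-1])
    grad_norm = float(np.linalg.norm(g))
    if grad_norm > 1e-6:
        raise RuntimeError(
            f"fit_ml did not reach a stationary point: |grad| = {grad_norm:.3e} "
            f"after BFGS ({res.nit} iters) and {n_newton} Newton steps"
        )

    H = _num_hessian(y, X, theta)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"observed information not invertible: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    if not np.isfinite(se).all() or (se <= 0).any():
        raise RuntimeError("observed-information standard errors are not positive")

    return BetaRegFit(
        beta=theta[:-1],
        phi=float(theta[-1]),
        se_beta=se[:-1],
        se_phi=float(se[-1]),
        loglik=_loglik_arrays(y, X, theta[:-1], theta[-1]),
        grad_norm=grad_norm,
        n_iter=int(res.nit) + n_newton,
    )


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


def _log_post(y, X, beta, phi, priors: BetaRegPriors) -> float:
    ll = _loglik_arrays(y, X, beta, phi)
    if not np.isfinite(ll):
        return -np.inf
    lp = -0.5 * float(beta @ beta) / priors.beta_prior_sd**2
    lp += (priors.phi_prior_shape - 1.0) * np.log(phi) - priors.phi_prior_rate * phi
    return ll + lp


def run_beta_mcmc(
    data: BetaRegData,
    priors: BetaRegPriors,
    settings: McmcSettings,
) -> BetaRegDraws:
    """Metropolis-within-Gibbs sampler for the beta regression posterior.

    One block random-walk update on ``beta`` (multivariate normal proposal
    whose covariance tracks the empirical draw covariance) and one scalar
    random walk on ``log phi``.  Both proposal scales adapt toward a target
    acceptance rate during burn-in only, and are frozen afterwards so the
    retained chain is Markovian.  Overflowing proposals get likelihood
    ``-inf`` and are rejected.
    """
    rng = np.random.default_rng(settings.seed)
    y, X = data.y, data.X
    k = data.n_coef

    beta = np.zeros(k)
    beta[0] = logit(float(np.mean(y)))
    mu0 = float(np.mean(y))
    var0 = max(float(np.var(y)), 1e-8)
    phi = max(mu0 * (1.0 - mu0) / var0 - 1.0, 1.0)
    logphi = np.log(phi)

    lp = _log_post(y, X, beta, phi, priors)

    scale_beta = 0.1
    scale_phi = 0.3
    chol = np.linalg.cholesky(np.linalg.inv(X.T @ X + 1e-8 * np.eye(k)))
    hist = np.empty((settings.n_burn if settings.n_burn else 1, k))

    n_keep = settings.n_retained
    beta_out = np.empty((n_keep, k))
    phi_out = np.empty(n_keep)
    kept = 0
    acc_beta = acc_phi = 0
    post_burn = 0

    for it in range(settings.n_iter):
        in_burn = it < settings.n_burn

        prop = beta + scale_beta * (chol @ rng.standard_normal(k))
        lp_prop = _log_post(y, X, prop, phi, priors)
        accepted = np.log(rng.uniform()) < lp_prop - lp
        if accepted:
            beta, lp = prop, lp_prop
        if not in_burn:
            acc_beta += accepted

        prop_logphi = logphi + scale_phi * rng.standard_normal()
        phi_prop = np.exp(prop_logphi)
        lp_prop = _log_post(y, X, beta, phi_prop, priors)
        # extra log(phi) terms: Jacobian of the log transform
        ratio = (lp_prop + prop_logphi) - (lp + logphi)
        accepted_phi = np.isfinite(lp_prop) and np.log(rng.uniform()) < ratio
        if accepted_phi:
            phi, logphi, lp = phi_prop, prop_logphi, lp_prop
        if not in_burn:
            acc_phi += accepted_phi
            post_burn += 1

        if in_burn:
            hist[it] = beta
            # Robbins-Monro scale adaptation toward target acceptance
            step = 2.0 / (1.0 + it) ** 0.6
            scale_beta *= np.exp(step * ((1.0 if accepted else 0.0) - 0.30))
            scale_phi *= np.exp(step * ((1.0 if accepted_phi else 0.0) - 0.40))
            if it >= 200 and (it + 1) % 200 == 0:
                cov = np.cov(hist[max(0, it - 1000): it + 1].T)
                cov = np.atleast_2d(cov) + 1e-10 * np.eye(k)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass  # keep previous proposal shape

        if (it + 1) % 1000 == 0:
            logger.info("betareg iter %d/%d log-posterior %.3f", it + 1, settings.n_iter, lp)

        if not in_burn and (it - settings.n_burn) % settings.thin == 0:
            beta_out[kept] = beta
            phi_out[kept] = phi
            kept += 1

    return BetaRegDraws(
        beta_draws=beta_out[:kept],
        phi_draws=phi_out[:kept],
        accept_rate_beta=acc_beta / max(post_burn, 1),
        accept_rate_phi=acc_phi / max(post_burn, 1),
        coef_names=data.coef_names,
    )
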