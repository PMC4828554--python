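"""Bayesian stochastic frontier estimation by Gibbs sampling.

Model
-----
For observation ``i`` (one unit in one period)::

    y_i = x_i' beta + v_i - u_i,   v_i ~ Normal(0, sigma2),   u_i >= 0

with ``u_i`` half-normal: ``u_i = |z_i|`` for ``z_i ~ Normal(0, lambda)``
(``lambda`` is the variance of the underlying normal).  Priors are
``beta_j ~ Normal(0, sigma_beta^2)``, ``sigma2^-1 ~ Gamma(a0, b0)`` and
``lambda^-1 ~ Gamma(c, d)``.  Treating the latent ``u`` as parameters makes
every full conditional a standard distribution, so the posterior is explored
with a plain Gibbs sampler (data augmentation).

Technical efficiency of an observation is ``exp(-u_i)``; a unit's score is
the average over its periods of the posterior means of ``exp(-u_i)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NumericalError",
    "PanelDataset",
    "FrontierPriors",
    "McmcSettings",
    "FrontierDraws",
    "EfficiencyTable",
    "full_conditional_beta",
    "full_conditional_u",
    "full_conditional_noise_precision",
    "full_conditional_ineff_precision",
    "sample_truncated_normal_nonneg",
    "run_gibbs",
    "technical_efficiency",
    "rank_efficiency",
]

logger = logging.getLogger(__name__)


class NumericalError(RuntimeError):
    """Raised when a linear-algebra step fails (e.g. singular conditional)."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class PanelDataset:
    """Balanced unit-by-period panel with a design matrix.

    ``X`` carries a leading intercept column and a trailing integer trend
    column (the period index); the stochastic covariates sit in between and
    are the only columns written to CSV (intercept and trend are
    reconstructed on read).
    """

    units: np.ndarray
    periods: np.ndarray
    y: np.ndarray
    X: np.ndarray
    x_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=object)
        self.periods = np.asarray(self.periods, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.shape[0]
        if not (self.units.shape[0] == self.periods.shape[0] == n == self.X.shape[0]):
            raise ValueError("units, periods, y and X must have equal length")
        if not np.isfinite(self.y).all() or not np.isfinite(self.X).all():
            raise ValueError("panel contains non-finite values")
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one column")
        # tiny oracle instances may carry a bare design without const/trend
        if not self.x_names and self.X.shape[1] >= 2:
            self.x_names = [f"x{j}" for j in range(1, self.X.shape[1] - 1)]
        if self.X.shape[1] >= 2 and len(self.x_names) != self.X.shape[1] - 2:
            raise ValueError("x_names must name the non-intercept, non-trend columns")
        self._check_balanced()

    def _check_balanced(self) -> None:
        ref: tuple | None = None
        for unit in self.unit_labels:
            per = tuple(sorted(self.periods[self.units == unit]))
            if ref is None:
                ref = per
            elif per != ref:
                raise ValueError(f"panel is unbalanced: unit {unit!r} has periods {per}, expected {ref}")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def unit_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self.units:
            seen.setdefault(u)
        return list(seen)

    @property
    def coef_names(self) -> list[str]:
        if self.X.shape[1] == 1:
            return ["b1"]
        return ["const", *self.x_names, "trend"]

    def to_frame(self) -> pd.DataFrame:
        cols = {"unit": self.units, "period": self.periods, "y": self.y}
        for j, name in enumerate(self.x_names, start=1):
            cols[name] = self.X[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PanelDataset":
        required = {"unit", "period", "y"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
        x_names = [c for c in frame.columns if c not in required]
        n = len(frame)
        X = np.column_stack(
            [np.ones(n)]
            + [frame[c].to_numpy(dtype=float) for c in x_names]
            + [frame["period"].to_numpy(dtype=float)]
        )
        return cls(
            units=frame["unit"].to_numpy(dtype=object),
            periods=frame["period"].to_numpy(dtype=int),
            y=frame["y"].to_numpy(dtype=float),
            X=X,
            x_names=list(x_names),
        )

    @classmethod
    def read_csv(cls, path) -> "PanelDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class FrontierPriors:
    """Hyperparameters of the frontier priors (all strictly positive)."""

    beta_prior_sd: float = 100.0
    noise_precision_shape: float = 0.001
    noise_precision_rate: float = 0.001
    ineff_precision_shape: float = 0.01
    ineff_precision_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "beta_prior_sd",
            "noise_precision_shape",
            "noise_precision_rate",
            "ineff_precision_shape",
            "ineff_precision_rate",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class McmcSettings:
    n_iter: int
    n_burn: int
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("require 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class FrontierDraws:
    """Retained posterior draws from :func:`run_gibbs`."""

    beta_draws: np.ndarray  # (draws, n_coef)
    sigma2_draws: np.ndarray  # (draws,)
    lambda_draws: np.ndarray  # (draws,)
    u_draws: np.ndarray  # (draws, n_obs)
    coef_names: list[str]

    def __post_init__(self) -> None:
        if (self.u_draws < 0).any():
            raise ValueError("latent inefficiency draws must be nonnegative")
        if (self.sigma2_draws <= 0).any() or (self.lambda_draws <= 0).any():
            raise ValueError("variance draws must be strictly positive")

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    def params_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.beta_draws, columns=self.coef_names)
        frame["sigma2"] = self.sigma2_draws
        frame["lambda"] = self.lambda_draws
        return frame


@dataclass
class EfficiencyTable:
    """Per-unit efficiency scores with dense ranks 1..N."""

    units: np.ndarray
    scores: np.ndarray
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)
        n = len(self.units)
        if sorted(self.ranks) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..N")
        if not ((self.scores > 0) & (self.scores <= 1)).all():
            raise ValueError("scores must lie in (0, 1]")
        order = np.argsort(self.ranks)
        if (np.diff(self.scores[order]) > 1e-15).any():
            raise ValueError("scores must be non-increasing in rank")

    def rank_of(self, unit: str) -> int:
        idx = np.nonzero(self.units == unit)[0]
        if idx.size != 1:
            raise KeyError(unit)
        return int(self.ranks[idx[0]])

    def score_of(self, unit: str) -> float:
        idx = np.nonzero(self.units == unit)[0]
        if idx.size != 1:
            raise KeyError(unit)
        return float(self.scores[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"country": self.units, "score": self.scores, "rank": self.ranks})
        return frame.sort_values("rank").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EfficiencyTable":
        frame = pd.read_csv(path)
        return cls(
            units=frame["country"].to_numpy(dtype=object),
            scores=frame["score"].to_numpy(dtype=float),
            ranks=frame["rank"].to_numpy(dtype=int),
        )


# ---------------------------------------------------------------------------
# full conditionals
# ---------------------------------------------------------------------------


def full_conditional_beta(
    data: PanelDataset,
    u: np.ndarray,
    sigma2: float,
    priors: FrontierPriors,
) -> tuple[np.ndarray, np.ndarray]:
    """Normal full conditional of the frontier coefficients.

    Given the augmented outcome ``y~ = y + u`` the conditional is
    ``Normal(m, V)`` with ``V = (X'X/sigma2 + I/sigma_beta^2)^-1`` and
    ``m = V X'y~ / sigma2``.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[0] != data.n_obs:
        raise ValueError("u must have one entry per observation")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    X = data.X
    prec = X.T @ X / sigma2 + np.eye(data.n_coef) / priors.beta_prior_sd**2
    try:
        V = np.linalg.inv(prec)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"singular coefficient conditional: {exc}") from exc
    if not np.isfinite(V).all():
        raise NumericalError("coefficient conditional covariance is not finite")
    mean = V @ (X.T @ (data.y + u)) / sigma2
    V = (V + V.T) / 2.0
    return mean, V


def full_conditional_u(
    residual_base: np.ndarray,
    sigma2: float,
    lam: float,
) -> tuple[np.ndarray, float]:
    """Truncated-normal full conditional of the latent inefficiencies.

    ``residual_base[i] = x_i'beta - y_i``.  The conditional of ``u_i`` is
    Normal(mu*_i, omega2) truncated to [0, inf) with
    ``omega2 = (1/sigma2 + 1/lambda)^-1`` and ``mu*_i = omega2 r_i / sigma2``.
    """
    if sigma2 <= 0 or lam <= 0:
        raise ValueError("sigma2 and lambda must be strictly positive")
    r = np.asarray(residual_base, dtype=float)
    omega2 = 1.0 / (1.0 / sigma2 + 1.0 / lam)
    mu_star = omega2 * r / sigma2
    return mu_star, omega2


def full_conditional_noise_precision(
    data: PanelDataset,
    beta: np.ndarray,
    u: np.ndarray,
    priors: FrontierPriors,
) -> tuple[float, float]:
    """Gamma(shape, rate) full conditional of the noise precision 1/sigma2."""
    resid = data.y - data.X @ np.asarray(beta, dtype=float) + np.asarray(u, dtype=float)
    shape = priors.noise_precision_shape + data.n_obs / 2.0
    rate = priors.noise_precision_rate + 0.5 * float(resid @ resid)
    return shape, rate


def full_conditional_ineff_precision(
    u: np.ndarray,
    priors: FrontierPriors,
) -> tuple[float, float]:
    """Gamma(shape, rate) full conditional of the inefficiency precision 1/lambda."""
    u = np.asarray(u, dtype=float)
    if (u < 0).any():
        raise ValueError("u must be nonnegative elementwise")
    shape = priors.ineff_precision_shape + u.shape[0] / 2.0
    rate = priors.ineff_precision_rate + 0.5 * float(u @ u)
    return shape, rate


def sample_truncated_normal_nonneg(mu, var, rng: np.random.Generator):
    """Draw from Normal(mu, var) truncated to [0, inf).

    Vectorized over ``mu``.  Delegates to :class:`scipy.stats.truncnorm`,
    whose sampler is tail-safe even for ``mu`` around ``-10*sqrt(var)``.
    """
    var = np.asarray(var, dtype=float)
    if (var <= 0).any():
        raise ValueError("var must be strictly positive")
    mu = np.asarray(mu, dtype=float)
    sd = np.sqrt(var)
    a = (0.0 - mu) / sd
    draw = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=mu.shape, random_state=rng)
    return np.maximum(draw, 0.0)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _log_joint(data, beta, sigma2, lam, u, priors) -> float:
    # unnormalized log posterior, only for liveness logging
    resid = data.y - data.X @ beta + u
    n = data.n_obs
    out = -0.5 * n * np.log(sigma2) - 0.5 * float(resid @ resid) / sigma2
    out += -0.5 * n * np.log(lam) - 0.5 * float(u @ u) / lam
    out += -0.5 * float(beta @ beta) / priors.beta_prior_sd**2
    out += stats.gamma.logpdf(1.0 / sigma2, priors.noise_precision_shape, scale=1.0 / priors.noise_precision_rate)
    out += stats.gamma.logpdf(1.0 / lam, priors.ineff_precision_shape, scale=1.0 / priors.ineff_precision_rate)
    return out


def run_gibbs(
    data: PanelDataset,
    priors: FrontierPriors,
    settings: McmcSettings,
) -> FrontierDraws:
    """Gibbs sampler with data augmentation for the frontier model.

    Each iteration updates, in this fixed order: the latent inefficiencies
    ``u`` (truncated normal), the coefficients ``beta`` (multivariate
    normal), the noise precision (Gamma) and the inefficiency precision
    (Gamma).  Initial values are deterministic: ``beta`` at OLS, ``u`` at
    0.01, ``sigma2`` at the OLS residual variance and ``lambda`` at 0.1.
    Post-burn-in draws are retained every ``thin`` iterations.
    """
    rng = np.random.default_rng(settings.seed)
    X, y = data.X, data.y
    n, k = data.n_obs, data.n_coef

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = max(float(resid @ resid) / max(n - k, 1), 1e-8)
    lam = 0.1
    u = np.full(n, 0.01)

    n_keep = settings.n_retained
    beta_out = np.empty((n_keep, k))
    sigma2_out = np.empty(n_keep)
    lambda_out = np.empty(n_keep)
    u_out = np.empty((n_keep, n))

    kept = 0
    for it in range(settings.n_iter):
        try:
            mu_star, omega2 = full_conditional_u(X @ beta - y, sigma2, lam)
            u = sample_truncated_normal_nonneg(mu_star, omega2, rng)

            mean, V = full_conditional_beta(data, u, sigma2, priors)
            beta = mean + np.linalg.cholesky(V) @ rng.standard_normal(k)

            shape, rate = full_conditional_noise_precision(data, beta, u, priors)
            sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)

            shape, rate = full_conditional_ineff_precision(u, priors)
            lam = 1.0 / rng.gamma(shape, 1.0 / rate)
        except (np.linalg.LinAlgError, NumericalError, ValueError) as exc:
            raise NumericalError(f"Gibbs update failed at iteration {it}: {exc}") from exc

        if (it + 1) % 1000 == 0:
            logger.info(
                "gibbs iter %d/%d log-posterior %.3f",
                it + 1,
                settings.n_iter,
                _log_joint(data, beta, sigma2, lam, u, priors),
            )

        if it >= settings.n_burn and (it - settings.n_burn) % settings.thin == 0:
            beta_out[kept] = beta
            sigma2_out[kept] = sigma2
            lambda_out[kept] = lam
            u_out[kept] = u
            kept += 1

    return FrontierDraws(
        beta_draws=beta_out[:kept],
        sigma2_draws=sigma2_out[:kept],
        lambda_draws=lambda_out[:kept],
        u_draws=u_out[:kept],
        coef_names=data.coef_names,
    )


# ---------------------------------------------------------------------------
# efficiency scores and ranking
# ---------------------------------------------------------------------------


def technical_efficiency(draws: FrontierDraws, data: PanelDataset) -> EfficiencyTable:
    """Posterior-mean technical efficiency per unit, with dense ranks.

    Per-observation efficiency is the posterior mean of ``exp(-u_i)``; a
    unit's score averages its per-observation efficiencies across periods.
    """
    if draws.n_draws == 0:
        raise ValueError("draws must be non-empty")
    eff_obs = np.exp(-draws.u_draws).mean(axis=0)
    scores = {unit: float(eff_obs[data.units == unit].mean()) for unit in data.unit_labels}
    return rank_efficiency(scores)


def rank_efficiency(scores: Mapping[str, float] | pd.Series | Sequence[tuple[str, float]]) -> EfficiencyTable:
    """Dense ranks 1..N by decreasing score; exact ties break alphabetically."""
    if isinstance(scores, pd.Series):
        pairs = list(zip(scores.index.astype(str), scores.to_numpy(dtype=float)))
    elif isinstance(scores, Mapping):
        pairs = [(str(k), float(v)) for k, v in scores.items()]
    else:
        pairs = [(str(k), float(v)) for k, v in scores]
    labels = [p[0] for p in pairs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate unit labels: {dupes}")
    for label, score in pairs:
        if not 0 < score <= 1:
            raise ValueError(f"score for {label!r} must lie in (0, 1], got {score}")
    ordered = sorted(pairs, key=lambda p: (-p[1], p[0]))
    return EfficiencyTable(
        units=np.array([p[0] for p in ordered], dtype=object),
        scores=np.array([p[1] for p in ordered]),
        ranks=np.arange(1, len(ordered) + 1),
    )
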