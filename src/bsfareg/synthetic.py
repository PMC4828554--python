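"""Synthetic data generators with known ground truth.

Every downstream stage is tested against data from this module: a balanced
frontier panel with normal noise and half-normal inefficiency, and
beta-distributed responses given a logit-linear mean.  Each generator
consumes one seed and draws its random pieces in a fixed, documented order
(covariates, then noise, then inefficiency) so identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from bsfareg.betareg import BetaRegData
from bsfareg.sfa import PanelDataset

__all__ = [
    "TrueFrontierParams",
    "TrueBetaRegParams",
    "simulate_frontier_panel",
    "simulate_beta_outcomes",
    "simulate_indicator_design",
    "write_truth_sidecar",
]


@dataclass(frozen=True)
class TrueFrontierParams:
    """Ground-truth frontier parameters.

    ``beta`` covers intercept + stochastic covariates + trend (in that
    order); ``lambda_u`` is the variance of the underlying normal of the
    half-normal inefficiency, so E[u] = sqrt(2 lambda_u / pi).
    """

    beta: tuple[float, ...]
    sigma_v: float
    lambda_u: float
    seed: int = 0

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim != 1 or beta.shape[0] < 2:
            raise ValueError("beta must be a vector: intercept [+ covariates] + trend")
        if not np.isfinite(beta).all():
            raise ValueError("beta must be finite")
        if not self.sigma_v > 0:
            raise ValueError("sigma_v must be strictly positive")
        if self.lambda_u < 0:
            raise ValueError("lambda_u must be nonnegative")

    @property
    def beta_arr(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)


@dataclass(frozen=True)
class TrueBetaRegParams:
    """Ground-truth beta-regression parameters (logit-scale coefficients)."""

    beta: tuple[float, ...]
    phi: float
    seed: int = 0

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim != 1 or not np.isfinite(beta).all():
            raise ValueError("beta must be a finite vector")
        if not self.phi > 0:
            raise ValueError("phi must be strictly positive")

    @property
    def beta_arr(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)


def simulate_frontier_panel(
    n_units: int,
    n_periods: int,
    params: TrueFrontierParams,
) -> tuple[PanelDataset, np.ndarray]:
    """Balanced panel from the frontier model, plus the true inefficiencies.

    Design: leading intercept, ``len(beta) - 2`` standard-normal covariates,
    and a deterministic 1..n_periods trend column.  Outcome is
    ``X beta + v - u`` with ``v ~ Normal(0, sigma_v^2)`` and
    ``u = |Normal(0, lambda_u)|``.
    """
    if n_units < 1 or n_periods < 1:
        raise ValueError("n_units and n_periods must be positive")
    rng = np.random.default_rng(params.seed)
    beta = params.beta_arr
    n = n_units * n_periods
    n_x = beta.shape[0] - 2

    x = rng.standard_normal((n, n_x))
    v = rng.normal(0.0, params.sigma_v, n)
    u = np.abs(rng.normal(0.0, math.sqrt(params.lambda_u), n))

    trend = np.tile(np.arange(1, n_periods + 1), n_units)
    units = np.repeat([f"U{i:03d}" for i in range(1, n_units + 1)], n_periods)
    X = np.column_stack([np.ones(n), x, trend.astype(float)])
    y = X @ beta + v - u

    data = PanelDataset(units=units, periods=trend, y=y, X=X)
    return data, u


def simulate_beta_outcomes(design: np.ndarray, params: TrueBetaRegParams) -> BetaRegData:
    """Beta-distributed responses for a given intercept-led design.

    ``mu = expit(X beta)`` and ``y ~ Beta(mu phi, (1 - mu) phi)``.  Draws
    that underflow to exactly 0 or 1 are redrawn (the density lives on the
    open interval), so the output never touches the boundary.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("design must be 2-D with an intercept plus >= 1 column")
    if not np.isfinite(X).all():
        raise ValueError("design must be finite")
    beta = params.beta_arr
    if beta.shape[0] != X.shape[1]:
        raise ValueError(f"beta length {beta.shape[0]} does not match design width {X.shape[1]}")

    rng = np.random.default_rng(params.seed)
    mu = special.expit(X @ beta)
    y = rng.beta(mu * params.phi, (1.0 - mu) * params.phi)
    for _ in range(100):
        bad = (y <= 0.0) | (y >= 1.0)
        if not bad.any():
            break
        y[bad] = rng.beta(mu[bad] * params.phi, (1.0 - mu[bad]) * params.phi)
    else:  # pragma: no cover - would need a pathological phi
        raise RuntimeError("could not draw responses off the (0,1) boundary")

    units = np.array([f"U{i:03d}" for i in range(1, X.shape[0] + 1)], dtype=object)
    return BetaRegData(units=units, y=y, X=X)


def simulate_indicator_design(n_units: int, n_indicators: int, seed: int = 0) -> np.ndarray:
    """Intercept-led design of integer policy-indicator scores in 0..6."""
    if n_units < 1 or n_indicators < 1:
        raise ValueError("n_units and n_indicators must be positive")
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 7, size=(n_units, n_indicators)).astype(float)
    return np.column_stack([np.ones(n_units), scores])


def write_truth_sidecar(path, u_true: np.ndarray, data: PanelDataset) -> None:
    """Per-observation ground-truth inefficiencies next to a panel CSV."""
    pd.DataFrame({"unit": data.units, "period": data.periods, "u_true": u_true}).to_csv(
        path, index=False
    )
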