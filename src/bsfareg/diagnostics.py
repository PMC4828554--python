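"""Posterior summarization and chain diagnostics.

The Monte Carlo error of a posterior mean uses the batch-means estimator
with ``B = floor(sqrt(n))`` batches; the convergence rule accepts a chain
when that error is below 5% of the posterior standard deviation.  A
covariate is flagged a "related factor" when its central 95% credible
interval excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PosteriorSummary",
    "mc_error",
    "summarize",
    "convergence_ok",
    "related_factor",
    "summaries_to_frame",
]


@dataclass(frozen=True)
class PosteriorSummary:
    node: str
    mean: float
    sd: float
    mc_error: float
    median: float
    q2_5: float
    q97_5: float
    n_retained: int
    start: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.mc_error < 0:
            raise ValueError("sd and mc_error must be nonnegative")
        if not self.q2_5 <= self.median <= self.q97_5:
            raise ValueError("quantiles must satisfy q2.5 <= median <= q97.5")


def mc_error(chain: np.ndarray) -> float:
    """Batch-means Monte Carlo standard error of the chain mean.

    Splits the chain into ``B = floor(sqrt(n))`` batches of equal length
    (dropping the remainder at the end) and returns the standard deviation
    of the batch means divided by ``sqrt(B)``.
    """
    chain = np.asarray(chain, dtype=float)
    n = chain.shape[0]
    if n < 20:
        raise ValueError(f"chain too short for batch means: n = {n} < 20")
    if np.ptp(chain) == 0:  # constant chain: exactly zero, no fp residue
        return 0.0
    n_batches = math.floor(math.sqrt(n))
    batch_len = n // n_batches
    means = chain[: n_batches * batch_len].reshape(n_batches, batch_len).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_batches))


def summarize(chain: np.ndarray, label: str, start: int = 0) -> PosteriorSummary:
    """Mean/SD/MC-error/quantile summary of one scalar chain."""
    chain = np.asarray(chain, dtype=float)
    if chain.shape[0] < 20:
        raise ValueError(f"chain too short to summarize: n = {chain.shape[0]} < 20")
    q2_5, median, q97_5 = np.quantile(chain, [0.025, 0.5, 0.975])
    return PosteriorSummary(
        node=label,
        mean=float(chain.mean()),
        sd=float(chain.std(ddof=1)),
        mc_error=mc_error(chain),
        median=float(median),
        q2_5=float(q2_5),
        q97_5=float(q97_5),
        n_retained=int(chain.shape[0]),
        start=int(start),
    )


def convergence_ok(summary: PosteriorSummary) -> bool:
    """True when the MC error is under 5% of the posterior SD.

    A degenerate chain (sd == 0) passes only with a zero MC error.
    """
    if summary.sd == 0:
        return summary.mc_error == 0
    return summary.mc_error < 0.05 * summary.sd


def related_factor(summary: PosteriorSummary) -> bool:
    """True when the 95% credible interval [q2.5, q97.5] excludes zero.

    Zero sitting exactly on an endpoint counts as included (not related).
    """
    return summary.q2_5 > 0 or summary.q97_5 < 0


def summaries_to_frame(summaries: list[PosteriorSummary]) -> pd.DataFrame:
    """Table-style frame: one row per node, WinBUGS-like column order."""
    return pd.DataFrame(
        {
            "node": [s.node for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
            "mc_error": [s.mc_error for s in summaries],
            "q2.5": [s.q2_5 for s in summaries],
            "median": [s.median for s in summaries],
            "q97.5": [s.q97_5 for s in summaries],
            "start": [s.start for s in summaries],
            "sample": [s.n_retained for s in summaries],
        }
    )
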