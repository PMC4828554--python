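"""Two-stage pipeline orchestration: config, CSV artifacts, manifest.

Stage 1 runs the frontier Gibbs sampler on a panel and writes a posterior
summary, the per-unit efficiency table and the retained parameter draws.
Stage 2 joins the efficiency scores to a policy-indicator table by unit
label, runs the beta-regression MCMC and writes a summary whose ``related``
column flags indicators with a zero-excluding 95% credible interval.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bsfareg import __version__ as _pkg_version
from bsfareg.betareg import BetaRegData, BetaRegDraws, BetaRegPriors, run_beta_mcmc
from bsfareg.diagnostics import (
    PosteriorSummary,
    related_factor,
    convergence_ok,
    summaries_to_frame,
    summarize,
)
from bsfareg.sfa import (
    EfficiencyTable,
    FrontierDraws,
    FrontierPriors,
    McmcSettings,
    PanelDataset,
    run_gibbs,
    technical_efficiency,
)
from bsfareg.synthetic import (
    TrueBetaRegParams,
    TrueFrontierParams,
    simulate_beta_outcomes,
    simulate_frontier_panel,
    simulate_indicator_design,
)

__all__ = [
    "PipelineConfig",
    "ConvergenceError",
    "run_stage1",
    "run_stage2",
    "run_two_stage",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised in strict mode when a monitored node violates the 5% MC-error rule."""


@dataclass(frozen=True)
class SyntheticPanelSpec:
    n_units: int = 29
    n_periods: int = 13
    beta: tuple[float, ...] = (4.3, 0.05, 0.02, 0.01)
    sigma_v: float = 0.05
    lambda_u: float = 0.1
    seed: int = 0


@dataclass(frozen=True)
class SyntheticIndicatorSpec:
    n_indicators: int = 20
    seed: int = 0


@dataclass
class PipelineConfig:
    out_dir: Path = Path("results")
    strict_convergence: bool = False
    panel_csv: Path | None = None
    indicators_csv: Path | None = None
    synthetic_panel: SyntheticPanelSpec | None = None
    synthetic_indicators: SyntheticIndicatorSpec | None = None
    frontier_priors: FrontierPriors = field(default_factory=FrontierPriors)
    betareg_priors: BetaRegPriors = field(default_factory=BetaRegPriors)
    stage1_mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(37500, 12000, 1, 0))
    stage2_mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(48000, 9500, 1, 0))

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.panel_csv is None and self.synthetic_panel is None:
            raise ValueError("stage 1 needs either panel_csv or a synthetic block")
        if self.panel_csv is not None and not Path(self.panel_csv).exists():
            raise ValueError(f"panel CSV not found: {self.panel_csv}")
        if self.indicators_csv is not None and not Path(self.indicators_csv).exists():
            raise ValueError(f"indicators CSV not found: {self.indicators_csv}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        def respath(v):
            if v is None:
                return None
            p = Path(v)
            return p if p.is_absolute() or base_dir is None else base_dir / p

        s1 = raw.get("stage1", {})
        s2 = raw.get("stage2", {})
        syn1 = s1.get("synthetic")
        syn2 = s2.get("synthetic")
        if syn1 is not None and "beta" in syn1:
            syn1 = {**syn1, "beta": tuple(syn1["beta"])}
        kwargs = dict(
            out_dir=Path(raw.get("out_dir", "results")),
            strict_convergence=bool(raw.get("strict_convergence", False)),
            panel_csv=respath(s1.get("panel_csv")),
            indicators_csv=respath(s2.get("indicators_csv")),
            synthetic_panel=SyntheticPanelSpec(**syn1) if syn1 is not None else None,
            synthetic_indicators=SyntheticIndicatorSpec(**syn2) if syn2 is not None else None,
        )
        if "priors" in s1:
            kwargs["frontier_priors"] = FrontierPriors(**s1["priors"])
        if "priors" in s2:
            kwargs["betareg_priors"] = BetaRegPriors(**s2["priors"])
        if "mcmc" in s1:
            kwargs["stage1_mcmc"] = McmcSettings(**s1["mcmc"])
        if "mcmc" in s2:
            kwargs["stage2_mcmc"] = McmcSettings(**s2["mcmc"])
        return cls(**kwargs)


def _load_panel(config: PipelineConfig) -> PanelDataset:
    if config.panel_csv is not None:
        return PanelDataset.read_csv(config.panel_csv)
    spec = config.synthetic_panel
    params = TrueFrontierParams(
        beta=spec.beta, sigma_v=spec.sigma_v, lambda_u=spec.lambda_u, seed=spec.seed
    )
    data, _ = simulate_frontier_panel(spec.n_units, spec.n_periods, params)
    return data


def _check_convergence(summaries: list[PosteriorSummary], strict: bool, stage: str) -> None:
    bad = [s.node for s in summaries if not convergence_ok(s)]
    for node in bad:
        logger.warning("%s: MC error of node %r exceeds 5%% of its SD", stage, node)
    if strict and bad:
        raise ConvergenceError(f"{stage}: convergence rule violated for nodes {bad}")


def run_stage1(
    config: PipelineConfig,
) -> tuple[FrontierDraws, EfficiencyTable, list[PosteriorSummary]]:
    """Frontier stage: Gibbs sampling, efficiency scoring, summary CSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = _load_panel(config)
    settings = config.stage1_mcmc
    draws = run_gibbs(data, config.frontier_priors, settings)
    table = technical_efficiency(draws, data)

    params = draws.params_frame()
    start = settings.n_burn
    summaries = [summarize(params[c].to_numpy(), c, start) for c in params.columns]
    _check_convergence(summaries, config.strict_convergence, "stage1")

    params.to_csv(out / "stage1_draws.csv", index=False)
    summaries_to_frame(summaries).to_csv(out / "stage1_summary.csv", index=False)
    table.to_csv(out / "efficiency.csv")
    return draws, table, summaries


def _squeeze_unit_boundary(scores: np.ndarray) -> np.ndarray:
    # (y (n-1) + 0.5) / n pulls boundary scores into the open interval
    n = scores.shape[0]
    return (scores * (n - 1) + 0.5) / n


def run_stage2(
    scores: EfficiencyTable,
    indicators: pd.DataFrame,
    config: PipelineConfig,
    squeeze_boundary: bool = False,
) -> tuple[BetaRegDraws, list[PosteriorSummary], list[str]]:
    """Regression stage: join scores to indicators, run MCMC, flag factors.

    ``squeeze_boundary`` applies the (y(n-1)+0.5)/n transformation to every
    score when any score sits exactly at 1.0 (possible for frontier-stage
    output); without it a boundary score is an error.
    """
    if "unit" not in indicators.columns:
        raise ValueError("indicator table must have a 'unit' column")
    ind_units = indicators["unit"].astype(str).to_list()
    score_units = [str(u) for u in scores.units]
    missing = sorted(set(score_units) ^ set(ind_units))
    if len(set(ind_units)) != len(ind_units) or missing:
        raise ValueError(f"unit mismatch between scores and indicators: {missing or 'duplicate units'}")

    y = np.array([scores.score_of(u) for u in ind_units], dtype=float)
    if ((y <= 0) | (y > 1)).any():
        raise ValueError("scores must lie in (0, 1]")
    if (y == 1.0).any():
        if not squeeze_boundary:
            bad = [u for u, s in zip(ind_units, y) if s == 1.0]
            raise ValueError(f"boundary score 1.0 for units {bad}: beta likelihood undefined")
        logger.warning(
            "boundary efficiency score(s) present; applying (y(n-1)+0.5)/n to ALL scores"
        )
        y = _squeeze_unit_boundary(y)

    x_names = [c for c in indicators.columns if c not in ("unit", "score")]
    if not x_names:
        raise ValueError("indicator table has no indicator columns")
    X = np.column_stack(
        [np.ones(len(ind_units))] + [indicators[c].to_numpy(dtype=float) for c in x_names]
    )
    data = BetaRegData(units=np.array(ind_units, dtype=object), y=y, X=X, x_names=list(x_names))

    settings = config.stage2_mcmc
    draws = run_beta_mcmc(data, config.betareg_priors, settings)

    params = draws.params_frame()
    start = settings.n_burn
    summaries = [summarize(params[c].to_numpy(), c, start) for c in params.columns]
    _check_convergence(summaries, config.strict_convergence, "stage2")
    related = [s.node for s in summaries if s.node in data.x_names and related_factor(s)]

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params.to_csv(out / "stage2_draws.csv", index=False)
    frame = summaries_to_frame(summaries)
    frame = frame.rename(columns={"node": "variable"})[
        ["variable", "mean", "sd", "mc_error", "q2.5", "q97.5"]
    ]
    frame["related"] = [related_factor(s) for s in summaries]
    frame.to_csv(out / "stage2_summary.csv", index=False)
    return draws, summaries, related


def _indicator_table(config: PipelineConfig, units: list[str]) -> pd.DataFrame:
    if config.indicators_csv is not None:
        return pd.read_csv(config.indicators_csv)
    spec = config.synthetic_indicators or SyntheticIndicatorSpec()
    design = simulate_indicator_design(len(units), spec.n_indicators, spec.seed)
    frame = pd.DataFrame(
        design[:, 1:], columns=[f"X{j}" for j in range(1, spec.n_indicators + 1)]
    )
    frame.insert(0, "unit", units)
    return frame


def run_two_stage(config: PipelineConfig) -> dict:
    """Full pipeline; returns a manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    draws1, table, summaries1 = run_stage1(config)
    indicators = _indicator_table(config, [str(u) for u in table.units])
    draws2, summaries2, related = run_stage2(table, indicators, config, squeeze_boundary=True)

    manifest = {
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": _config_to_jsonable(config),
        "related_factors": related,
        "artifacts": [
            "stage1_draws.csv",
            "stage1_summary.csv",
            "efficiency.csv",
            "stage2_draws.csv",
            "stage2_summary.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _config_to_jsonable(config: PipelineConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {f.name: conv(getattr(config, f.name)) for f in dataclasses.fields(config)}
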