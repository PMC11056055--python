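"""The simulation experiment: scenario grid, replications, aggregation, validation.

The full study design crosses ten spatial with ten temporal correlation
values (0.05, 0.15, ..., 0.95), runs 1000 replications per scenario, fits the
four models by NUTS at the study chain configuration, and averages WAIC, RMSE
and MAE per scenario and model.  The validation arm fits only the ANOVA model
(SPAM) on a 70% training split per replication and records the coverage of
95% posterior-predictive intervals on the held-out 30%.

Everything here scales down cleanly: reduced correlation grids, replication
counts, panel dimensions and the ``desk`` chain profile reproduce the
qualitative model ordering on one core in minutes.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .graphs import temporal_adjacency
from .mcmc import ChainConfig, chain_profile, run_chain
from .models import MODEL_NAMES, PanelData, PriorConfig, build_model
from .simulate import Scenario, generate_panel, train_test_split

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(round(0.05 + 0.1 * i, 2) for i in range(10))

METRIC_COLUMNS = [
    "scenario_sp", "scenario_tm", "model", "replication",
    "waic", "lpd", "p_waic", "rmse", "mae", "cp", "failed",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one simulation experiment (comparison or validation)."""

    sp_grid: tuple[float, ...] = DEFAULT_GRID
    tm_grid: tuple[float, ...] = DEFAULT_GRID
    n_reps: int = 1000
    models: tuple[str, ...] = MODEL_NAMES
    profile: str = "study"
    base_seed: int = 0
    n_units: int = 54
    n_times: int = 20
    train_fraction: float = 0.7
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.sp_grid or not self.tm_grid:
            raise ValueError("correlation grids must be non-empty")
        if any(not 0 < v < 1 for v in (*self.sp_grid, *self.tm_grid)):
            raise ValueError("grid values must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        unknown = set(m.upper() for m in self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")

    def chain_config(self, seed: int) -> ChainConfig:
        return chain_profile(self.profile, seed=seed)


def derive_seed(base_seed: int, sp: float, tm: float, rep: int) -> int:
    """Stable per-(scenario, replication) seed below 2^31."""
    ss = np.random.SeedSequence(
        [int(base_seed), int(round(sp * 1000)), int(round(tm * 1000)), int(rep)]
    )
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def scenario_grid(config: ExperimentConfig) -> list[Scenario]:
    """Cartesian product of the correlation grids (sp outer, tm inner)."""
    return [
        Scenario(
            sp=sp, tm=tm, n_units=config.n_units, n_times=config.n_times,
            seed=derive_seed(config.base_seed, sp, tm, 0),
        )
        for sp, tm in itertools.product(config.sp_grid, config.tm_grid)
    ]


def run_replication(
    scenario: Scenario,
    models: tuple[str, ...],
    chain_config: ChainConfig,
    seed: int,
    priors: PriorConfig | None = None,
    validation: bool = False,
    train_fraction: float = 0.7,
) -> list[dict]:
    """Generate one panel and fit each requested model on it.

    Returns one metric row per model.  In validation mode the likelihood is
    restricted to a random train fraction of the records and the row carries
    the test-set coverage percentage instead of WAIC/RMSE/MAE being the focus.
    A model whose chain fails is flagged ``failed`` without affecting others.
    """
    rng = np.random.default_rng(seed)
    panel = generate_panel(scenario, rng)
    tgraph = temporal_adjacency(scenario.n_times)
    mask = None
    split = None
    if validation:
        split = train_test_split(panel, train_fraction, rng)
        mask = np.zeros(panel.n_records, dtype=bool)
        mask[split.train_index] = True
        mask = mask.reshape(panel.y.shape)
    data = PanelData(
        y=panel.y, offset=panel.offset, X=panel.X,
        graph=panel.graph, tgraph=tgraph, mask=mask,
    )
    rows = []
    for name in models:
        row = {
            "scenario_sp": scenario.sp, "scenario_tm": scenario.tm,
            "model": name, "replication": seed,
            "waic": np.nan, "lpd": np.nan, "p_waic": np.nan,
            "rmse": np.nan, "mae": np.nan, "cp": np.nan, "failed": 0,
        }
        try:
            model = build_model(name, data, priors)
            cfg = dataclasses.replace(chain_config, seed=seed)
            draws = run_chain(model, cfg)
            if validation:
                cov = metrics.coverage(
                    draws, model, split.test_index,
                    rng=np.random.default_rng(seed + 10_000_019),
                )
                row["cp"] = cov.cp
            else:
                w = metrics.waic(draws.pointwise_loglik)
                yhat = metrics.point_predictions(draws, model)
                row.update(
                    waic=w.waic, lpd=w.lpd, p_waic=w.p_waic,
                    rmse=metrics.rmse(panel.y, yhat),
                    mae=metrics.mae(panel.y, yhat),
                )
        except Exception:
            logger.exception(
                "model %s failed on scenario (%.2f, %.2f) seed %d",
                name, scenario.sp, scenario.tm, seed,
            )
            row["failed"] = 1
        rows.append(row)
    return rows


def _grid_rows(config: ExperimentConfig, validation: bool) -> pd.DataFrame:
    out_path = None
    done: set[tuple] = set()
    existing: list[pd.DataFrame] = []
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        name = "validation_metrics.csv" if validation else "metrics.csv"
        out_path = out_dir / name
        if out_path.exists():
            prev = pd.read_csv(out_path)
            existing.append(prev)
            done = {
                (r.scenario_sp, r.scenario_tm, r.model, r.replication)
                for r in prev.itertuples()
            }
    models = tuple(m.upper() for m in config.models)
    if validation:
        models = ("SPAM",)
    rows: list[dict] = []
    for sp, tm in itertools.product(config.sp_grid, config.tm_grid):
        for rep in range(config.n_reps):
            seed = derive_seed(config.base_seed, sp, tm, rep)
            todo = [m for m in models if (sp, tm, m, seed) not in done]
            if not todo:
                continue
            scenario = Scenario(
                sp=sp, tm=tm, n_units=config.n_units, n_times=config.n_times,
                seed=seed,
            )
            new = run_replication(
                scenario, tuple(todo), config.chain_config(seed), seed,
                validation=validation, train_fraction=config.train_fraction,
            )
            rows.extend(new)
            if out_path is not None:
                pd.DataFrame(new)[METRIC_COLUMNS].to_csv(
                    out_path, mode="a", header=not out_path.exists(), index=False
                )
    frames = existing + ([pd.DataFrame(rows)[METRIC_COLUMNS]] if rows else [])
    if not frames:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["scenario_sp", "scenario_tm", "model", "replication"])
        .reset_index(drop=True)
    )


def aggregate(rows: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean (and sd) of the metrics per scenario and model.

    Failed replications are excluded from the averages; their count is
    reported in ``n_failed``.
    """
    ok = rows[rows["failed"] == 0]
    agg = (
        ok.groupby(["scenario_sp", "scenario_tm", "model"])
        .agg(
            waic=("waic", "mean"), waic_sd=("waic", "std"),
            rmse=("rmse", "mean"), rmse_sd=("rmse", "std"),
            mae=("mae", "mean"), mae_sd=("mae", "std"),
            cp=("cp", "mean"), n_reps=("waic", "size"),
        )
        .reset_index()
    )
    failures = (
        rows.groupby(["scenario_sp", "scenario_tm", "model"])["failed"]
        .sum()
        .rename("n_failed")
        .reset_index()
    )
    return agg.merge(failures, on=["scenario_sp", "scenario_tm", "model"])


def run_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Full comparison experiment: per-replication metric rows for all models.

    Writes an incremental tidy CSV when ``config.out_dir`` is set and resumes
    from it (completed scenario/replication/model rows are skipped).
    Aggregate with :func:`aggregate`.
    """
    return _grid_rows(config, validation=False)


def run_validation(config: ExperimentConfig) -> pd.DataFrame:
    """Coverage validation of SPAM with a 70/30 record split per replication."""
    return _grid_rows(config, validation=True)


def rank_models(agg: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Order models by mean WAIC within each scenario; count wins per model.

    Ties break by mean RMSE, then model name.  Returns (ranked table with a
    ``rank`` column, win counts indexed by model).
    """
    if agg["model"].nunique() < 2:
        raise ValueError("need at least two models to rank")
    ranked = (
        agg.sort_values(["scenario_sp", "scenario_tm", "waic", "rmse", "model"])
        .assign(
            rank=lambda d: d.groupby(["scenario_sp", "scenario_tm"]).cumcount() + 1
        )
        .reset_index(drop=True)
    )
    wins = (
        ranked[ranked["rank"] == 1]
        .groupby("model")
        .size()
        .reindex(sorted(agg["model"].unique()), fill_value=0)
    )
    return ranked, wins


def heatmap_table(agg: pd.DataFrame, model: str, metric: str = "waic") -> pd.DataFrame:
    """Scenario-grid matrix of one metric for one model (rows sp, columns tm)."""
    sub = agg[agg["model"] == model]
    return sub.pivot(index="scenario_sp", columns="scenario_tm", values=metric)
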