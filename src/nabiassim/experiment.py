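"""Grid orchestration, aggregation and reporting.

A run sweeps a grid of NA prevalences ``p`` (fraction of subjects with
the trait) and intensities ``q`` (average fraction of items affected).
For every grid cell, ``n_populations`` null populations of ``n_subjects``
are drawn from the item marginals, the NA mechanism is applied, the three
regressions are fitted, and the cell is summarised by

* the mean unadjusted R^2 per model (reported as a percentage),
* the fraction of populations in which each coefficient is significant
  at the 5% level (plus the joint effort-and-reward fraction), and
* the mean and SD of the four derived scores (log GHQ, effort, reward,
  ERI ratio).

Reproducibility contract: population ``i`` always uses the generator
seeded by ``(master_seed, i)``, independent of cell order, so cells can
be computed in any order (or in parallel) with identical results, and the
same population index is coupled across cells through shared random
numbers — the baseline column is bit-identical for every ``p`` at
``q = 0``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .inference import ALL_MODELS, ModelId, RegressionResult, build_design, fit_linear_model, predictor_names
from .instruments import ItemSpec, canonical_items, score_population
from .marginal_model import MarginalTable, ScaleTargets, build_reference_marginals, sample_population
from .na_bias import NAConfig, inject_na

__all__ = [
    "RunConfig",
    "PopulationRecord",
    "ModelCellStats",
    "GridCellSummary",
    "run_population",
    "run_cell",
    "run_grid",
    "interpret_r2",
    "Interpretation",
    "write_tables",
    "summaries_to_frame",
    "summaries_from_frame",
]

logger = logging.getLogger("nabiassim")

DEFAULT_P_GRID = (0.0, 0.05, 0.10, 0.20)
DEFAULT_Q_GRID = (0.0, 0.10, 0.20, 0.30, 0.40)
SCORE_NAMES = ("log_ghq", "effort", "reward", "eri_ratio")

#: interpretation bands for an observed explained variance (percent)
R2_CAUTION_MAX = 5.0
R2_UNLIKELY_MAX = 10.0


@dataclass(frozen=True)
class RunConfig:
    """Full description of one simulation run."""

    n_subjects: int = 300
    n_populations: int = 10_000
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID
    models: tuple[ModelId, ...] = ALL_MODELS
    master_seed: int = 0
    log_offset: float = 0.0
    marginals_source: str = "reference"
    sd_mode: str = "pooled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_grid", tuple(float(p) for p in self.p_grid))
        object.__setattr__(self, "q_grid", tuple(float(q) for q in self.q_grid))
        object.__setattr__(self, "models", tuple(ModelId(m) for m in self.models))
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        for grid, name in ((self.p_grid, "p_grid"), (self.q_grid, "q_grid")):
            if not grid:
                raise ValueError(f"{name} must be non-empty")
            if any(not 0.0 <= g <= 1.0 for g in grid):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if len(set(self.models)) != len(self.models):
            raise ValueError("duplicate model in models")
        if self.log_offset < 0:
            raise ValueError("log_offset must be non-negative")
        if self.sd_mode not in ("pooled", "across_populations"):
            raise ValueError("sd_mode must be 'pooled' or 'across_populations'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = [m.value for m in self.models]
        d["p_grid"] = list(self.p_grid)
        d["q_grid"] = list(self.q_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("config file must contain a flat mapping")
        return cls.from_dict(d)

    def resolve_marginals(self, item_specs: Sequence[ItemSpec] | None = None) -> MarginalTable:
        if self.marginals_source == "reference":
            return build_reference_marginals(ScaleTargets(), item_specs)
        return MarginalTable.read_csv(self.marginals_source, item_specs)


@dataclass(frozen=True)
class PopulationRecord:
    """Everything retained from one simulated population."""

    population_index: int
    na_config: NAConfig
    results: dict[ModelId, RegressionResult]
    score_means: dict[str, float]
    score_vars: dict[str, float]  # within-population subject variance (ddof=1)
    ghq_offset_used: float


@dataclass(frozen=True)
class ModelCellStats:
    mean_r2_pct: float
    prop_significant: dict[str, float]
    prop_both_significant: float | None
    n_excluded: int


@dataclass(frozen=True)
class GridCellSummary:
    p_subject: float
    q_items: float
    n_populations: int
    model_stats: dict[ModelId, ModelCellStats]
    score_means: dict[str, float]
    score_sds: dict[str, float]
    sd_mode: str = "pooled"


def population_rng(master_seed: int, population_index: int) -> np.random.Generator:
    """The reproducible substream for one population index."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(population_index),))
    return np.random.default_rng(ss)


def run_population(marginals: MarginalTable, config: RunConfig, na_config: NAConfig,
                   population_index: int) -> PopulationRecord:
    """Simulate, bias, score and fit one population.

    Fully determined by ``(config.master_seed, population_index)`` and the
    inputs; the NA uniforms are drawn from the same substream immediately
    after the response uniforms, giving shared random numbers across NA
    conditions.
    """
    rng = population_rng(config.master_seed, population_index)
    pop = sample_population(marginals, config.n_subjects, rng)
    pop = inject_na(pop, na_config, marginals.specs, rng)
    offset = config.log_offset
    try:
        scored = score_population(pop, marginals.specs, log_offset=offset)
    except ValueError:
        # a GHQ score of exactly 0 occurred with a zero offset; fall back
        # to log(score + 1) for this population
        offset = 1.0
        scored = score_population(pop, marginals.specs, log_offset=offset)
    results: dict[ModelId, RegressionResult] = {}
    for model_id in config.models:
        y, X = build_design(scored, model_id)
        results[model_id] = fit_linear_model(y, X, model_id)
    means = {name: float(scored[name].mean()) for name in SCORE_NAMES}
    variances = {name: float(scored[name].var(ddof=1)) for name in SCORE_NAMES}
    return PopulationRecord(
        population_index=population_index,
        na_config=na_config,
        results=results,
        score_means=means,
        score_vars=variances,
        ghq_offset_used=offset,
    )


def _aggregate(records: list[PopulationRecord], config: RunConfig,
               na_config: NAConfig) -> GridCellSummary:
    model_stats: dict[ModelId, ModelCellStats] = {}
    for model_id in config.models:
        kept = [r.results[model_id] for r in records if not r.results[model_id].excluded]
        n_excluded = len(records) - len(kept)
        if kept:
            mean_r2 = 100.0 * float(np.mean([res.r_squared for res in kept]))
            props = {
                name: float(np.mean([res.significant[name] for res in kept]))
                for name in predictor_names(model_id)
            }
            both = (
                float(np.mean([res.both_significant for res in kept]))
                if model_id is ModelId.EFFORT_REWARD
                else None
            )
        else:
            mean_r2 = float("nan")
            props = {name: float("nan") for name in predictor_names(model_id)}
            both = float("nan") if model_id is ModelId.EFFORT_REWARD else None
        model_stats[model_id] = ModelCellStats(mean_r2, props, both, n_excluded)

    score_means = {
        name: float(np.mean([r.score_means[name] for r in records])) for name in SCORE_NAMES
    }
    score_sds = {}
    for name in SCORE_NAMES:
        if config.sd_mode == "pooled":
            # subject-level SD: average within-population variance
            score_sds[name] = float(np.sqrt(np.mean([r.score_vars[name] for r in records])))
        else:
            means = [r.score_means[name] for r in records]
            score_sds[name] = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return GridCellSummary(
        p_subject=na_config.p_subject,
        q_items=na_config.q_items,
        n_populations=len(records),
        model_stats=model_stats,
        score_means=score_means,
        score_sds=score_sds,
        sd_mode=config.sd_mode,
    )


def run_cell(marginals: MarginalTable, config: RunConfig, na_config: NAConfig,
             stream_path=None) -> GridCellSummary:
    """Aggregate ``config.n_populations`` populations for one (p, q) cell.

    ``stream_path`` optionally receives a long-format CSV with one row
    per (population, model) carrying full-precision R^2 and p-values.
    """
    records = [
        run_population(marginals, config, na_config, i) for i in range(config.n_populations)
    ]
    if stream_path is not None:
        rows = []
        for r in records:
            for model_id, res in r.results.items():
                row = {
                    "population_id": r.population_index,
                    "p_subject": na_config.p_subject,
                    "q_items": na_config.q_items,
                    "model_id": model_id.value,
                    "r2": res.r_squared,
                    "excluded": res.excluded,
                }
                for name in predictor_names(model_id):
                    row[f"coef_{name}"] = res.coefficients[name]
                    row[f"p_{name}"] = res.p_values[name]
                    row[f"sig_{name}"] = res.significant[name]
                if res.both_significant is not None:
                    row["both_significant"] = res.both_significant
                rows.append(row)
        pd.DataFrame(rows).to_csv(stream_path, index=False)
    return _aggregate(records, config, na_config)


def run_grid(config: RunConfig, marginals: MarginalTable | None = None) -> list[GridCellSummary]:
    """One :class:`GridCellSummary` per (p, q) cell of the configured grid."""
    if marginals is None:
        marginals = config.resolve_marginals()
    summaries = []
    n_cells = len(config.p_grid) * len(config.q_grid)
    done = 0
    for p in config.p_grid:
        for q in config.q_grid:
            done += 1
            logger.info("cell %d/%d: p=%g q=%g", done, n_cells, p, q)
            try:
                summaries.append(run_cell(marginals, config, NAConfig(p, q)))
            except Exception as exc:
                raise RuntimeError(f"grid cell (p={p}, q={q}) failed: {exc}") from exc
    return summaries


@dataclass(frozen=True)
class Interpretation:
    """Band verdict for an observed explained variance, plus the weakest
    NA configurations whose simulated mean R^2 reaches it."""

    observed_r2_pct: float
    band: str
    model_id: ModelId
    minimal_cells: tuple[tuple[float, float], ...]


def _r2_band(r2_pct: float) -> str:
    if r2_pct <= R2_CAUTION_MAX:
        return "caution"
    if r2_pct < R2_UNLIKELY_MAX:
        return "possibly_na_unlikely"
    return "not_likely_na"


def interpret_r2(observed_r2_percent: float, grid: Sequence[GridCellSummary],
                 model_id: ModelId = ModelId.LOG_RATIO) -> Interpretation:
    """Place an observed R^2 (percent) against the simulated NA grid.

    The band follows the rule of thumb calibrated by the simulation:
    explained variance <= 5% should be treated with caution (NA alone can
    produce it), 5-10% may still result from NA though that is unlikely,
    and >= 10% is not likely to be an NA artefact.  ``minimal_cells`` are
    the Pareto-minimal (p, q) settings whose simulated mean R^2 reaches
    the observed value — "how much NA it would take".
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    model_id = ModelId(model_id)
    reaching = [
        (s.p_subject, s.q_items)
        for s in grid
        if model_id in s.model_stats
        and np.isfinite(s.model_stats[model_id].mean_r2_pct)
        and s.model_stats[model_id].mean_r2_pct >= observed_r2_percent
    ]
    minimal = tuple(
        sorted(
            (p, q)
            for p, q in reaching
            if not any(
                (p2 <= p and q2 <= q and (p2, q2) != (p, q)) for p2, q2 in reaching
            )
        )
    )
    return Interpretation(
        observed_r2_pct=float(observed_r2_percent),
        band=_r2_band(float(observed_r2_percent)),
        model_id=model_id,
        minimal_cells=minimal,
    )


def summaries_to_frame(summaries: Sequence[GridCellSummary]) -> pd.DataFrame:
    """Tidy long-format frame: one row per (cell, kind, model, statistic)."""
    rows = []
    for s in summaries:
        for model_id, st in s.model_stats.items():
            rows.append((s.p_subject, s.q_items, "model", model_id.value, "mean_r2_pct",
                         st.mean_r2_pct))
            for name, prop in st.prop_significant.items():
                rows.append((s.p_subject, s.q_items, "model", model_id.value,
                             f"prop_sig_{name}", prop))
            if st.prop_both_significant is not None:
                rows.append((s.p_subject, s.q_items, "model", model_id.value,
                             "prop_sig_both", st.prop_both_significant))
            rows.append((s.p_subject, s.q_items, "model", model_id.value, "n_excluded",
                         float(st.n_excluded)))
        for name in SCORE_NAMES:
            rows.append((s.p_subject, s.q_items, "score", name, "mean", s.score_means[name]))
            rows.append((s.p_subject, s.q_items, "score", name, "sd", s.score_sds[name]))
        rows.append((s.p_subject, s.q_items, "meta", "", "n_populations",
                     float(s.n_populations)))
    return pd.DataFrame(rows, columns=["p_subject", "q_items", "kind", "name", "stat", "value"])


def summaries_from_frame(df: pd.DataFrame) -> list[GridCellSummary]:
    """Inverse of :func:`summaries_to_frame` (scores, models and counts)."""
    summaries = []
    for (p, q), cell in df.groupby(["p_subject", "q_items"], sort=True):
        model_stats: dict[ModelId, ModelCellStats] = {}
        models = cell[cell["kind"] == "model"]
        for name, sub in models.groupby("name"):
            model_id = ModelId(name)
            stats = dict(zip(sub["stat"], sub["value"]))
            props = {
                k.removeprefix("prop_sig_"): v
                for k, v in stats.items()
                if k.startswith("prop_sig_") and k != "prop_sig_both"
            }
            model_stats[model_id] = ModelCellStats(
                mean_r2_pct=float(stats["mean_r2_pct"]),
                prop_significant=props,
                prop_both_significant=stats.get("prop_sig_both"),
                n_excluded=int(stats.get("n_excluded", 0)),
            )
        scores = cell[cell["kind"] == "score"]
        score_means, score_sds = {}, {}
        for name, sub in scores.groupby("name"):
            stats = dict(zip(sub["stat"], sub["value"]))
            score_means[name] = float(stats["mean"])
            score_sds[name] = float(stats["sd"])
        meta = cell[cell["kind"] == "meta"]
        n_pop = int(meta["value"].iloc[0]) if len(meta) else 0
        summaries.append(
            GridCellSummary(float(p), float(q), n_pop, model_stats, score_means, score_sds)
        )
    return summaries


_SCORE_FMT = {"log_ghq": 2, "effort": 1, "reward": 1, "eri_ratio": 3}
_SCORE_LABEL = {
    "log_ghq": "log GHQ-12 Likert score",
    "effort": "effort score",
    "reward": "reward score",
    "eri_ratio": "ERI ratio",
}


def _table1_frame(summaries: Sequence[GridCellSummary]) -> pd.DataFrame:
    qs = sorted({s.q_items for s in summaries})
    by_cell = {(s.p_subject, s.q_items): s for s in summaries}
    models = list(dict.fromkeys(m for s in summaries for m in s.model_stats))
    ps = sorted({s.p_subject for s in summaries})
    rows = []
    for model_id in models:
        for p in ps:
            row: dict = {"model": model_id.value, "p_subject": p}
            for q in qs:
                s = by_cell.get((p, q))
                if s is None or model_id not in s.model_stats:
                    continue
                st = s.model_stats[model_id]
                row[f"r2_pct_q{q:g}"] = round(st.mean_r2_pct, 2)
                if model_id is ModelId.EFFORT_REWARD:
                    e = st.prop_significant.get("effort", float("nan"))
                    r = st.prop_significant.get("reward", float("nan"))
                    er = st.prop_both_significant
                    row[f"prop_sig_q{q:g}"] = f"{e:.2f}/{r:.2f}/{er:.2f}"
                else:
                    (name,) = st.prop_significant
                    row[f"prop_sig_q{q:g}"] = f"{st.prop_significant[name]:.2f}"
            rows.append(row)
    return pd.DataFrame(rows)


def _table2_frame(summaries: Sequence[GridCellSummary]) -> pd.DataFrame:
    qs = sorted({s.q_items for s in summaries})
    ps = sorted({s.p_subject for s in summaries})
    by_cell = {(s.p_subject, s.q_items): s for s in summaries}
    rows = []
    for name in SCORE_NAMES:
        nd = _SCORE_FMT[name]
        for p in ps:
            row: dict = {"score": _SCORE_LABEL[name], "p_subject": p}
            for q in qs:
                s = by_cell.get((p, q))
                if s is None:
                    continue
                row[f"q{q:g}"] = f"{s.score_means[name]:.{nd}f} ({s.score_sds[name]:.{nd}f})"
            rows.append(row)
    return pd.DataFrame(rows)


def write_tables(summaries: Sequence[GridCellSummary], out_dir,
                 config: RunConfig | None = None) -> dict[str, Path]:
    """Write table1.csv, table2.csv, results_long.csv and a run manifest.

    ``table1.csv`` mirrors the R^2 / proportion-significant layout (rows =
    model x p, columns = q; the two-predictor proportions are formatted
    ``effort/reward/both``); ``table2.csv`` the mean (SD) score layout;
    ``results_long.csv`` keeps full precision.  Fails before writing
    anything if ``summaries`` is empty.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table1": out_dir / "table1.csv",
        "table2": out_dir / "table2.csv",
        "long": out_dir / "results_long.csv",
        "manifest": out_dir / "manifest.json",
    }
    _table1_frame(summaries).to_csv(paths["table1"], index=False)
    _table2_frame(summaries).to_csv(paths["table2"], index=False)
    summaries_to_frame(summaries).to_csv(paths["long"], index=False)
    manifest = {
        "package": "nabiassim",
        "version": _pkg_version,
        "config": config.to_dict() if config is not None else None,
        "n_cells": len(summaries),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
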