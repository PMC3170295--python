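import json

import numpy as np
import pytest
import yaml

from nabiassim.experiment import (
    GridCellSummary,
    ModelCellStats,
    RunConfig,
    interpret_r2,
    run_cell,
    run_grid,
    run_population,
    summaries_from_frame,
    summaries_to_frame,
    write_tables,
)
from nabiassim.inference import ModelId
from nabiassim.instruments import canonical_items
from nabiassim.marginal_model import MarginalTable
from nabiassim.na_bias import NAConfig


@pytest.fixture
def small_config():
    return RunConfig(n_subjects=60, n_populations=8, master_seed=123)


class TestRunConfig:
    def test_defaults_mirror_study_conditions(self):
        cfg = RunConfig()
        assert cfg.n_subjects == 300
        assert cfg.n_populations == 10_000
        assert cfg.p_grid == (0.0, 0.05, 0.10, 0.20)
        assert cfg.q_grid == (0.0, 0.10, 0.20, 0.30, 0.40)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 5},
            {"n_populations": 0},
            {"p_grid": (0.0, 1.5)},
            {"q_grid": ()},
            {"log_offset": -1.0},
            {"sd_mode": "bogus"},
            {"models": ("LOG_RATIO", "LOG_RATIO")},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RunConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(n_subjects=40, n_populations=3, master_seed=9,
                        p_grid=(0.0, 0.1), q_grid=(0.0, 0.2), models=("RATIO",))
        path = tmp_path / "config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
        assert RunConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            RunConfig.from_dict({"n_population": 5})


class TestRunPopulation:
    def test_deterministic_rerun(self, reference_marginals, small_config):
        a = run_population(reference_marginals, small_config, NAConfig(0, 0), 3)
        b = run_population(reference_marginals, small_config, NAConfig(0, 0), 3)
        assert a.score_means == b.score_means
        for m in small_config.models:
            assert a.results[m].r_squared == b.results[m].r_squared
            assert a.results[m].p_values == b.results[m].p_values

    def test_r_squared_in_unit_interval(self, reference_marginals, small_config):
        rec = run_population(reference_marginals, small_config, NAConfig(0.2, 0.4), 0)
        for res in rec.results.values():
            assert 0.0 <= res.r_squared <= 1.0

    def test_shared_seed_monotone_bias(self, reference_marginals, small_config):
        base = run_population(reference_marginals, small_config, NAConfig(0, 0), 5)
        biased = run_population(reference_marginals, small_config, NAConfig(0.2, 0.4), 5)
        assert biased.score_means["eri_ratio"] >= base.score_means["eri_ratio"]
        assert biased.score_means["log_ghq"] >= base.score_means["log_ghq"]
        assert biased.score_means["reward"] <= base.score_means["reward"]

    def test_ghq_zero_fallback_offset(self, items):
        """All-zero GHQ marginals force the log(score + 1) fallback."""
        probs = {}
        for s in items:
            p = np.zeros(s.n_levels)
            if s.item_id.startswith("ghq"):
                p[0] = 1.0
            else:
                p[:2] = 0.5
            probs[s.item_id] = p
        table = MarginalTable(probs, items)
        cfg = RunConfig(n_subjects=20, n_populations=1, models=(), master_seed=0)
        rec = run_population(table, cfg, NAConfig(0, 0), 0)
        assert rec.ghq_offset_used == 1.0
        assert rec.score_means["log_ghq"] == 0.0


class TestRunCell:
    def test_single_population_cell_equals_record(self, reference_marginals):
        cfg = RunConfig(n_subjects=60, n_populations=1, master_seed=7)
        rec = run_population(reference_marginals, cfg, NAConfig(0, 0), 0)
        cell = run_cell(reference_marginals, cfg, NAConfig(0, 0))
        for m in cfg.models:
            st = cell.model_stats[m]
            assert st.mean_r2_pct == pytest.approx(100 * rec.results[m].r_squared)
            for name, sig in rec.results[m].significant.items():
                assert st.prop_significant[name] == float(sig)
        for name, val in rec.score_means.items():
            assert cell.score_means[name] == pytest.approx(val)

    def test_stream_csv(self, reference_marginals, small_config, tmp_path):
        path = tmp_path / "stream.csv"
        run_cell(reference_marginals, small_config, NAConfig(0.1, 0.2), stream_path=path)
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == small_config.n_populations * len(small_config.models)
        assert {"population_id", "model_id", "r2"} <= set(df.columns)

    def test_sd_mode_flag(self, reference_marginals):
        pooled = RunConfig(n_subjects=60, n_populations=6, master_seed=1, sd_mode="pooled")
        across = RunConfig(n_subjects=60, n_populations=6, master_seed=1,
                           sd_mode="across_populations")
        a = run_cell(reference_marginals, pooled, NAConfig(0, 0))
        b = run_cell(reference_marginals, across, NAConfig(0, 0))
        # subject-level SD is ~sqrt(n) larger than the SD of population means
        assert a.score_sds["effort"] > 3 * b.score_sds["effort"]


class TestRunGrid:
    def test_default_grid_has_twenty_cells(self, reference_marginals):
        cfg = RunConfig(n_subjects=30, n_populations=2, master_seed=5)
        summaries = run_grid(cfg, reference_marginals)
        assert len(summaries) == 20
        assert {(s.p_subject, s.q_items) for s in summaries} == {
            (p, q) for p in cfg.p_grid for q in cfg.q_grid
        }

    def test_baseline_cells_identical_under_shared_seeds(self, reference_marginals):
        """(p, 0) cells are bit-identical to (0, 0): nothing shifts at q=0."""
        cfg = RunConfig(n_subjects=60, n_populations=5, master_seed=2,
                        p_grid=(0.0, 0.05, 0.2), q_grid=(0.0,))
        summaries = run_grid(cfg, reference_marginals)
        base = summaries[0]
        for s in summaries[1:]:
            assert s.score_means == base.score_means
            for m in cfg.models:
                assert s.model_stats[m].mean_r2_pct == base.model_stats[m].mean_r2_pct
                assert s.model_stats[m].prop_significant == base.model_stats[m].prop_significant


def _toy_grid():
    def cell(p, q, r2):
        stats = {
            ModelId.LOG_RATIO: ModelCellStats(r2, {"log_eri_ratio": 0.5}, None, 0)
        }
        return GridCellSummary(p, q, 10, stats,
                               {"log_ghq": 2.3, "effort": 12.5, "reward": 48.1,
                                "eri_ratio": 0.48},
                               {"log_ghq": 0.2, "effort": 1.9, "reward": 3.2,
                                "eri_ratio": 0.08})

    return [
        cell(0.0, 0.0, 0.34),
        cell(0.05, 0.4, 2.0),
        cell(0.1, 0.4, 5.1),
        cell(0.2, 0.3, 5.3),
        cell(0.2, 0.4, 11.3),
    ]


class TestInterpretR2:
    @pytest.mark.parametrize(
        "observed, band",
        [(3.0, "caution"), (6.0, "possibly_na_unlikely"), (12.0, "not_likely_na")],
    )
    def test_bands(self, observed, band):
        assert interpret_r2(observed, _toy_grid()).band == band

    def test_minimal_cells_are_pareto_frontier(self):
        res = interpret_r2(5.0, _toy_grid())
        # both (0.1, 0.4) and (0.2, 0.3) reach 5%, neither dominates the other;
        # (0.2, 0.4) is dominated by both
        assert res.minimal_cells == ((0.1, 0.4), (0.2, 0.3))

    def test_unreachable_r2_has_no_cells(self):
        assert interpret_r2(50.0, _toy_grid()).minimal_cells == ()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            interpret_r2(5.0, [])


class TestWriteTables:
    @pytest.fixture
    def summaries(self, reference_marginals):
        cfg = RunConfig(n_subjects=40, n_populations=3, master_seed=11,
                        p_grid=(0.0, 0.2), q_grid=(0.0, 0.4))
        return run_grid(cfg, reference_marginals), cfg

    def test_files_written(self, summaries, tmp_path):
        grid, cfg = summaries
        paths = write_tables(grid, tmp_path / "out", cfg)
        for path in paths.values():
            assert path.exists()
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["config"]["master_seed"] == 11

    def test_table1_layout(self, summaries, tmp_path):
        import pandas as pd

        grid, cfg = summaries
        paths = write_tables(grid, tmp_path / "out", cfg)
        t1 = pd.read_csv(paths["table1"])
        assert {"model", "p_subject", "r2_pct_q0", "r2_pct_q0.4",
                "prop_sig_q0", "prop_sig_q0.4"} <= set(t1.columns)
        assert len(t1) == len(cfg.models) * 2  # models x p values
        er = t1[t1["model"] == "EFFORT_REWARD"]
        assert er["prop_sig_q0"].str.count("/").eq(2).all()

    def test_long_csv_byte_identical_on_rerun(self, summaries, tmp_path):
        grid, cfg = summaries
        p1 = write_tables(grid, tmp_path / "a", cfg)
        p2 = write_tables(grid, tmp_path / "b", cfg)
        assert p1["long"].read_bytes() == p2["long"].read_bytes()

    def test_empty_summaries_write_nothing(self, tmp_path):
        out = tmp_path / "out"
        with pytest.raises(ValueError):
            write_tables([], out)
        assert not out.exists()

    def test_summaries_frame_round_trip(self, summaries):
        grid, _ = summaries
        back = summaries_from_frame(summaries_to_frame(grid))
        assert len(back) == len(grid)
        by_cell = {(s.p_subject, s.q_items): s for s in back}
        for s in grid:
            b = by_cell[(s.p_subject, s.q_items)]
            for m, st in s.model_stats.items():
                assert b.model_stats[m].mean_r2_pct == pytest.approx(st.mean_r2_pct)
                for name, prop in st.prop_significant.items():
                    assert b.model_stats[m].prop_significant[name] == pytest.approx(prop)
            for name, val in s.score_means.items():
                assert b.score_means[name] == pytest.approx(val)
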