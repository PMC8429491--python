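import numpy as np
import pandas as pd
import pytest

from myoregen import SimConfig
from myoregen.experiments import (
    damage_sweep,
    material_sensitivity,
    run_coupled,
    run_iteration,
    summarize,
    decline_onset,
    peak_tick,
    replicate_mean_series,
)


@pytest.fixture(scope="module")
def fast_cfg():
    return SimConfig(replicates=3, ticks=400, seed=42)


class TestRunIteration:
    def test_single_replicate_is_representative(self, small_bundle, fast_cfg):
        cfg = SimConfig(replicates=1, ticks=300, seed=1)
        res = run_iteration(small_bundle, cfg)
        assert res.representative == 0
        assert res.endpoint_grid is res.replicates[0].grid

    def test_summary_recomputable_from_replicates(self, small_bundle, fast_cfg):
        res = run_iteration(small_bundle, fast_cfg)
        ends = [r.census["fibril_count"].iloc[-1] for r in res.replicates]
        assert res.summary["fibril_mean"] == pytest.approx(
            np.mean(ends), abs=1e-9
        )
        assert res.summary["fibril_sd"] == pytest.approx(
            np.std(ends, ddof=1), abs=1e-9
        )

    def test_zero_damage_returns_initial_exactly(self, small_bundle):
        cfg = SimConfig(replicates=2, ticks=200, damage_fraction=0.0, seed=9)
        res = run_iteration(small_bundle, cfg)
        assert res.summary["fibril_mean"] == small_bundle.fibril_count
        assert res.summary["fibril_sd"] == 0.0

    def test_random_damage_placement_mode(self, small_bundle):
        cfg = SimConfig(replicates=1, ticks=120, seed=4)
        res = run_iteration(small_bundle, cfg, strain_source="random")
        assert res.replicates[0].injury_tick == 1

    def test_deterministic_under_master_seed(self, small_bundle):
        cfg = SimConfig(replicates=2, ticks=250, seed=77)
        a = run_iteration(small_bundle, cfg)
        b = run_iteration(small_bundle, cfg)
        assert a.summary == b.summary
        assert a.endpoint_grid == b.endpoint_grid


class TestRunCoupled:
    def test_one_iteration_equals_run_iteration(self, small_bundle, fast_cfg):
        single = run_iteration(small_bundle, fast_cfg,
                               rng=np.random.default_rng(fast_cfg.seed))
        coupled = run_coupled(small_bundle, fast_cfg, n_iterations=1)
        assert len(coupled) == 1
        assert coupled[0].summary == single.summary

    def test_iterations_chain_geometry(self, small_bundle, fast_cfg):
        results = run_coupled(small_bundle, fast_cfg, n_iterations=2)
        nxt = results[1].replicates[0].pre_injury_fibrils
        rep_end = results[0].endpoint_grid.fibril_count
        # next cycle starts from the representative endpoint geometry
        assert nxt == rep_end

    def test_invalid_iteration_count(self, small_bundle, fast_cfg):
        with pytest.raises(ValueError):
            run_coupled(small_bundle, fast_cfg, n_iterations=0)


class TestSummaries:
    def test_empty_results_give_empty_report(self, tmp_path):
        tables = summarize([], tmp_path)
        assert tables["iterations"].empty

    def test_report_columns_and_csv_output(self, small_bundle, fast_cfg, tmp_path):
        res = run_iteration(small_bundle, fast_cfg)
        tables = summarize([res], tmp_path)
        row = tables["iterations"].iloc[0]
        assert "clearance_time_h" in row and "repair_complete_time_h" in row
        assert (tmp_path / "iterations.csv").exists()
        assert (tmp_path / "census.csv").exists()
        mean_df = tables["census"]
        recomputed = (
            pd.concat([r.census for r in res.replicates])
            .groupby("tick")["fibril_count"].mean()
        )
        assert np.allclose(
            mean_df["fibril_count"].to_numpy(), recomputed.to_numpy(), atol=1e-9
        )


class TestSensitivityTable:
    def test_density_has_no_effect(self, bundle):
        table = material_sensitivity(bundle, seed=0)
        dens = table[table.parameter == "density"]
        assert (dens.pct_change_max_strain == 0).all()
        assert (dens.pct_change_min_strain == 0).all()

    def test_stiffer_along_fiber_modulus_lowers_strain(self, bundle):
        table = material_sensitivity(bundle, seed=0)
        c5 = table[table.parameter == "c5"].set_index("delta")
        assert c5.loc[0.10, "pct_change_max_strain"] < 0
        assert c5.loc[-0.10, "pct_change_max_strain"] > 0


class TestSeriesMetrics:
    def test_peak_and_onset_on_synthetic_series(self):
        t = np.arange(200, dtype=float)
        series = np.where(t <= 120, t, 240.0 - t)
        assert peak_tick(series) == 120
        onset = decline_onset(series)
        assert 115 <= onset <= 125

    def test_flat_series_never_declines(self):
        assert np.isnan(decline_onset(np.ones(50)))

    def test_replicate_mean_series_shape(self, small_bundle, fast_cfg):
        res = run_iteration(small_bundle, fast_cfg)
        mean_n = replicate_mean_series(res.replicates, "N")
        assert len(mean_n) == fast_cfg.ticks + 1


class TestCLI:
    def test_generate_strain_sensitivity_pipeline(self, tmp_path):
        from click.testing import CliRunner

        from myoregen.cli import main

        runner = CliRunner()
        grid_path = tmp_path / "grid.csv"
        r = runner.invoke(main, [
            "generate", "--n-fibers", "4", "--fibrils", "900",
            "--ecm-fraction", "0.2", "--seed", "3", "--out", str(grid_path),
        ])
        assert r.exit_code == 0, r.output
        strain_path = tmp_path / "strain.csv"
        r = runner.invoke(main, [
            "strain", "--grid", str(grid_path), "--out", str(strain_path),
        ])
        assert r.exit_code == 0, r.output
        assert strain_path.read_text().startswith("x,y,strain")
        r = runner.invoke(main, [
            "sensitivity", "--grid", str(grid_path),
            "--outdir", str(tmp_path / "sens"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "sens" / "sensitivity.csv").exists()

    def test_simulate_writes_manifest_and_tables(self, tmp_path):
        from click.testing import CliRunner

        from myoregen.cli import main

        runner = CliRunner()
        grid_path = tmp_path / "grid.csv"
        runner.invoke(main, [
            "generate", "--n-fibers", "4", "--fibrils", "900",
            "--ecm-fraction", "0.2", "--seed", "3", "--out", str(grid_path),
        ])
        outdir = tmp_path / "run"
        r = runner.invoke(main, [
            "simulate", "--grid", str(grid_path), "--seed", "5",
            "--replicates", "1", "--outdir", str(outdir),
        ])
        assert r.exit_code == 0, r.output
        assert (outdir / "manifest.txt").exists()
        assert (outdir / "iterations.csv").exists()
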