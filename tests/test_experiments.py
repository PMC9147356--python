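import numpy as np
import pandas as pd
import pytest

from confocal_ao.cli import cli_main
from confocal_ao.experiments import (
    ExperimentConfig,
    SimulatedBench,
    line_profile,
    run_comparison,
    run_experiment,
)

from conftest import small_config


def test_config_round_trips_through_text():
    cfg = small_config()
    again = ExperimentConfig.from_text(cfg.to_text())
    assert again == cfg
    assert ExperimentConfig.from_text(cfg.to_text() + "\n# a comment\n") == cfg
    with pytest.raises(ValueError):
        ExperimentConfig.from_text("not a key value line")


def test_manifest_round_trip_reproduces_run(tmp_path):
    """Every consumed parameter is in the manifest: a fresh run from the manifest
    alone reproduces the original run byte for byte."""
    cfg = small_config()
    res1 = run_experiment(cfg, out_dir=tmp_path / "a")
    cfg2 = ExperimentConfig.load(tmp_path / "a" / "manifest.txt")
    res2 = run_experiment(cfg2, out_dir=tmp_path / "b")
    assert (tmp_path / "a" / "run.csv").read_bytes() == (tmp_path / "b" / "run.csv").read_bytes()
    assert np.array_equal(res1.final_image, res2.final_image)


def test_run_determinism():
    cfg = small_config()
    r1 = run_experiment(cfg)
    r2 = run_experiment(cfg)
    assert np.array_equal(r1.run.final_u.u, r2.run.final_u.u)
    assert r1.final_metric == r2.final_metric


def test_artifacts_written(tmp_path):
    run_experiment(small_config(), out_dir=tmp_path)
    for name in (
        "run.csv",
        "manifest.txt",
        "initial.png",
        "final.png",
        "initial.tiff",
        "final.tiff",
        "residual_wavefront.tiff",
    ):
        assert (tmp_path / name).exists(), name
    df = pd.read_csv(tmp_path / "run.csv")
    assert list(df.columns) == ["k", "J_base", "J_plus", "J_minus", "delta_J", "gamma_k", "beta_k", "H_k"]
    assert len(df) == 12


def test_zero_aberration_run_does_not_invent_correction():
    cfg = small_config(aberration_rms=0.0)
    res = run_experiment(cfg)
    assert res.final_metric == pytest.approx(res.initial_metric, rel=0.10)
    assert float(np.sqrt(np.mean(res.run.final_u.u**2))) < 0.02


def test_table_one_parameters_echoed_in_manifest(tmp_path):
    """Fixed mode runs with |du|=0.005, gamma=5; adaptive with (0.005, 4, 0.9, 15, 5, 10)."""
    cfg = small_config()
    run_experiment(cfg, out_dir=tmp_path)
    text = (tmp_path / "manifest.txt").read_text()
    for line in (
        "spgd.perturbation_amplitude = 0.005",
        "spgd.gain = 5.0",
        "adaptive.gamma0 = 4.0",
        "adaptive.alpha = 0.9",
        "adaptive.xi = 15.0",
        "adaptive.history_window = 5",
        "adaptive.J_target = 10.0",
    ):
        assert line in text, line


def test_comparison_bookkeeping():
    from dataclasses import replace

    cfg = small_config()
    cfg = replace(cfg, spgd=replace(cfg.spgd, max_iterations=8))
    summ = run_comparison(cfg, [0, 1, 2], keep_results=False)
    assert len(summ.table) == 6
    assert set(summ.table["mode"]) == {"fixed", "adaptive"}
    agg = summ.aggregates()
    assert set(agg.index) == {"fixed", "adaptive"}
    with pytest.raises(ValueError):
        run_comparison(cfg, [])


def test_line_profile_contract():
    img = np.tile(np.arange(8.0), (8, 1))
    prof = line_profile(img, 3)
    assert prof.shape == (8,)
    assert np.array_equal(prof, np.arange(8.0))
    assert np.ptp(line_profile(np.full((4, 4), 2.0), 0)) == 0.0
    with pytest.raises(ValueError):
        line_profile(img, 8)


# ---- full-scale properties on the shared 20-seed experiment ----


def test_correction_reduces_residual_wavefront(paired_comparison):
    """Closed-loop efficacy: residual RMS below the initial 1.2 rad in >= 95% of runs."""
    t = paired_comparison.table
    assert (t["final_rms"] < t["initial_rms"]).mean() >= 0.95


def test_corrected_line_profiles_have_wider_range(paired_comparison):
    """After correction the grayscale profile through the brightest row spans a
    wider range, the simulated twin of brighter, more contrasted line scans."""
    hits = 0
    for seed in range(20):
        res = paired_comparison.results[(seed, "adaptive")]
        row = int(np.unravel_index(res.final_image.argmax(), res.final_image.shape)[0])
        before = line_profile(res.initial_image, row)
        after = line_profile(res.final_image, row)
        hits += np.ptp(after) > np.ptp(before)
    assert hits >= 18  # >= 90% of 20 seeds


def test_both_modes_improve_the_metric(paired_comparison):
    t = paired_comparison.table
    assert (t["final_metric"] > t["initial_metric"]).all()


# ---- command-line interface ----


def test_cli_correct_and_simulate(tmp_path):
    cfg_path = tmp_path / "bench.cfg"
    cfg_path.write_text(small_config().to_text())

    rc = cli_main(
        ["correct", "--mode", "adaptive", "--config", str(cfg_path), "--out", str(tmp_path / "run")]
    )
    assert rc == 0
    assert (tmp_path / "run" / "run.csv").exists()
    assert (tmp_path / "run" / "manifest.txt").exists()

    rc = cli_main(["simulate", "--config", str(cfg_path), "--out", str(tmp_path / "sim")])
    assert rc == 0
    assert (tmp_path / "sim" / "aberrated.png").exists()


def test_cli_compare_and_report(tmp_path):
    cfg_path = tmp_path / "bench.cfg"
    cfg_path.write_text(small_config().to_text())
    rc = cli_main(
        ["compare", "--seeds", "2", "--config", str(cfg_path), "--iterations", "6",
         "--out", str(tmp_path / "cmp")]
    )
    assert rc == 0
    table = pd.read_csv(tmp_path / "cmp" / "comparison.csv")
    assert len(table) == 4  # 2 seeds x 2 modes
    assert cli_main(["report", "--out", str(tmp_path)]) == 0


def test_cli_rejects_unknown_arguments(tmp_path):
    assert cli_main(["correct", "--no-such-flag"]) == 2
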