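"""Hypothesis catalogue, population drivers, calibration and configuration."""

import numpy as np
import pytest

from fibrilsim import ModelParams, catalogue, run_experiment, sweep_k2_epst
from fibrilsim.errors import CalibrationError, ConfigError
from fibrilsim.experiments import (DEFAULT_TARGETS, Hypothesis, calibrate,
                                   load_config, resolve_profile)


class TestCatalogue:
    def test_every_study_condition_is_present(self):
        cat = catalogue()
        for d in range(1, 16):
            assert f"III_{d}" in cat
        for name in ("III_1-3", "III_1-9", "III_1-3,11", "III_1-15",
                     "scrambled", "constant_min", "constant_mean",
                     "constant_max", "eps_t_half", "eps_t_double"):
            assert name in cat

    def test_replicate_counts_follow_the_study_design(self):
        cat = catalogue()
        assert cat["III_2"].n_sims == 100
        assert cat["III_11"].n_sims == 500
        assert cat["III_1-3"].n_sims == 500
        assert cat["III_1-15"].n_sims == 1000
        assert cat["scrambled"].n_sims == 1000
        assert cat["eps_t_half"].n_sims == 500

    def test_site_sets(self):
        cat = catalogue()
        assert cat["III_1-3,11"].site_set == frozenset({1, 2, 3, 11})
        assert cat["III_1-9"].site_set == frozenset(range(1, 10))

    def test_eps_scaling_variants(self):
        cat = catalogue()
        p = ModelParams()
        assert cat["eps_t_half"].scaled_params(p).eps_t == pytest.approx(7.5)
        assert cat["eps_t_double"].scaled_params(p).eps_t == pytest.approx(30.0)

    def test_invalid_hypotheses_rejected(self):
        with pytest.raises(ConfigError):
            Hypothesis("bad", frozenset({0}))
        with pytest.raises(ConfigError):
            Hypothesis("bad", frozenset({1}), stiffness_variant="nope")


class TestStiffnessVariants:
    def test_constant_variants_use_profile_extremes(self):
        p = ModelParams()
        rng = np.random.default_rng(0)
        base = np.asarray(Hypothesis("x", frozenset({1})).k0_values)
        for variant, target in (("constant_min", base.min()),
                                ("constant_mean", base.mean()),
                                ("constant_max", base.max())):
            hyp = Hypothesis("x", frozenset({1}), stiffness_variant=variant)
            prof = resolve_profile(hyp, p, rng)
            assert all(s.k0 == pytest.approx(target) for s in prof)

    def test_scrambled_permutes_same_values_per_seed(self):
        p = ModelParams()
        hyp = Hypothesis("x", frozenset({1}), stiffness_variant="scrambled")
        prof1 = resolve_profile(hyp, p, np.random.default_rng(3))
        prof2 = resolve_profile(hyp, p, np.random.default_rng(3))
        prof3 = resolve_profile(hyp, p, np.random.default_rng(4))
        k1 = [s.k0 for s in prof1]
        assert k1 == [s.k0 for s in prof2]          # same seed, same order
        assert sorted(k1) == sorted(s.k0 for s in prof3)  # same multiset
        assert k1 != [s.k0 for s in prof3]          # different order


@pytest.fixture(scope="module")
def fastp():
    return ModelParams(duration=40.0)


class TestRunExperiment:
    def test_smoke_run_writes_reproducible_rows(self, tmp_path, fastp):
        hyp = Hypothesis("smoke", frozenset({2}), n_sims=2, base_seed=5)
        res = run_experiment(hyp, fastp, out_dir=tmp_path,
                             summary_window=20.0)
        assert len(res["fibrils"]) == 2
        assert list(res["fibrils"]["seed"]) == [5, 6]
        res2 = run_experiment(hyp, fastp, summary_window=20.0)
        for col in ("n_fn", "L_r", "L_s", "f_sub"):
            assert np.allclose(res["fibrils"][col], res2["fibrils"][col])

    def test_resumable_by_seed_index(self, tmp_path, fastp):
        hyp = Hypothesis("resume", frozenset({2}), n_sims=2, base_seed=0)
        res1 = run_experiment(hyp, fastp, out_dir=tmp_path,
                              summary_window=20.0)
        hyp4 = hyp.with_(n_sims=4)
        res2 = run_experiment(hyp4, fastp, out_dir=tmp_path,
                              summary_window=20.0)
        assert len(res2["fibrils"]) == 4
        assert np.allclose(res2["fibrils"]["L_s"][:2], res1["fibrils"]["L_s"])

    def test_scale_reduces_replicates(self, fastp):
        hyp = Hypothesis("scaled", frozenset({2}), n_sims=100)
        res = run_experiment(hyp, fastp, scale=0.02, summary_window=20.0)
        assert len(res["fibrils"]) == 2

    def test_single_cell_sweep_degenerates_to_run_experiment(self, fastp):
        grid = sweep_k2_epst(fastp, k2_values=(0.8,), eps_t_values=(15.0,),
                             n_sims=2, base_seed=1)
        assert len(grid) == 1
        hyp = Hypothesis("III_2", frozenset({2}), n_sims=2, base_seed=1)
        ref = run_experiment(hyp, fastp,
                             summary_window=min(600.0, fastp.duration / 2))
        assert grid["n_fn_mean"][0] == pytest.approx(
            ref["fibrils"]["n_fn"].mean())
        assert grid["L_r_mean"][0] == pytest.approx(
            ref["fibrils"]["L_r"].mean())


class TestCalibrate:
    def test_passing_base_params_returned_unchanged(self):
        base = ModelParams()
        calls = []

        def fake_eval(p):
            calls.append(p)
            return {"allsite_n_fn": 416.0, "allsite_extensibility": 3.2,
                    "single_site_n_fn": 2.0}

        out = calibrate(base, search={"k_fn": [0.1, 0.2]},
                        evaluator=fake_eval)
        assert out is base
        assert len(calls) == 1

    def test_search_finds_first_passing_point(self):
        base = ModelParams()

        def fake_eval(p):
            ok = abs(p.k_fn - 0.2) < 1e-12
            return {"allsite_n_fn": 416.0 if ok else 10.0,
                    "allsite_extensibility": 3.2 if ok else 1.0,
                    "single_site_n_fn": 2.0}

        out = calibrate(base, search={"k_fn": [0.1, 0.2, 0.3]},
                        evaluator=fake_eval)
        assert out.k_fn == pytest.approx(0.2)

    def test_failure_carries_best_point(self):
        def fake_eval(p):
            return {"allsite_n_fn": 50.0, "allsite_extensibility": 1.2,
                    "single_site_n_fn": 30.0}

        with pytest.raises(CalibrationError) as exc:
            calibrate(ModelParams(), search={"k_fn": [0.1]},
                      evaluator=fake_eval)
        assert "scores" in exc.value.best

    def test_target_windows_match_study_means(self):
        lo, hi = DEFAULT_TARGETS["allsite_n_fn"]
        assert lo < 416 < hi
        elo, ehi = DEFAULT_TARGETS["allsite_extensibility"]
        assert elo < 3.23 < ehi


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        cfg.write_text(
            "model:\n  duration: 50.0\n  k_fn: 0.01\n"
            "hypothesis:\n  name: demo\n  site_set: [1, 2, 11]\n"
            "run:\n  n_sims: 3\n  base_seed: 7\n")
        doc = load_config(cfg)
        assert doc["params"].duration == 50.0
        assert doc["hypothesis"].site_set == frozenset({1, 2, 11})
        assert doc["hypothesis"].n_sims == 3
        assert doc["hypothesis"].base_seed == 7

    def test_catalogue_name_accepted(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        cfg.write_text("hypothesis: III_1-15\n")
        doc = load_config(cfg)
        assert doc["hypothesis"].site_set == frozenset(range(1, 16))

    def test_unknown_keys_rejected(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("model:\n  not_a_param: 1\n")
        with pytest.raises(ConfigError):
            load_config(cfg)
        cfg.write_text("extra_section: {}\n")
        with pytest.raises(ConfigError):
            load_config(cfg)


class TestCli:
    def test_run_command_writes_outputs(self, tmp_path):
        from click.testing import CliRunner

        from fibrilsim.cli import main
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "model:\n  duration: 30.0\n"
            "hypothesis:\n  name: mini\n  site_set: [2]\n  n_sims: 2\n")
        out = tmp_path / "out"
        result = CliRunner().invoke(
            main, ["run", "--config", str(cfg), "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert (out / "mini_fibrils.csv").exists()
        assert (out / "mini_runlog.json").exists()

    def test_analyze_command(self, tmp_path):
        from click.testing import CliRunner

        from fibrilsim.cli import main
        hyp = Hypothesis("ana", frozenset({2}), n_sims=3)
        run_experiment(hyp, ModelParams(duration=30.0), out_dir=tmp_path,
                       summary_window=15.0)
        result = CliRunner().invoke(
            main, ["analyze", "--in", str(tmp_path),
                   "--out", str(tmp_path / "tables")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "tables" / "ana_population.csv").exists()
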