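"""Workbench layer: presets, run configs, file output, CLI, and oracles."""
import json
import os

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from memadh import cli, config, oracles, presets
from memadh.models import ElectrolyteModel, PlanarGap

# small fast parameter bundle used where physics accuracy is not the point
FAST_EDL = dict(module="edl", task="solve",
                params=dict(salt_molar=0.1, sigma1=0.05, sigma2=-0.05,
                            gap_nm=2.0, n_nodes=2001))


class TestPresets:
    def test_all_presets_validate(self):
        for name in presets.list_presets():
            p = presets.get_preset(name)
            cfg = config.RunConfig(**p.config_dict())
            assert cfg.preset == name
            assert cfg.resolved_params() == p.params

    def test_yaml_round_trip(self, tmp_path):
        p = presets.get_preset("fig10_alpha5")
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump(p.config_dict()))
        cfg = config.load_config(str(path))
        assert cfg.module == "headgroup"
        assert cfg.resolved_params()["alpha"] == 5.0

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            presets.get_preset("fig99")

    def test_param_override_wins(self):
        cfg = config.RunConfig(module="headgroup", task="solve",
                               preset="fig10_alpha5",
                               params=dict(alpha=10.0))
        rp = cfg.resolved_params()
        assert rp["alpha"] == 10.0
        assert rp["sigma1"] == -0.30


class TestRunConfigValidation:
    def test_bad_task_for_module(self):
        with pytest.raises(ValueError, match="not available"):
            config.RunConfig(module="edl", task="minimize")

    def test_preset_module_mismatch(self):
        with pytest.raises(ValueError, match="belongs to module"):
            config.RunConfig(module="edl", task="solve",
                             preset="fig10_alpha5")

    def test_extra_keys_forbidden(self):
        with pytest.raises(Exception):
            config.RunConfig(module="edl", task="solve", typo_field=1)

    def test_non_mapping_config_file(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("- just\n- a\n- list\n")
        with pytest.raises(ValueError, match="mapping"):
            config.load_config(str(path))


class TestExecution:
    def test_writes_csv_and_json(self, tmp_path):
        cfg = config.RunConfig(**FAST_EDL,
                               output_prefix=str(tmp_path / "out" / "run"))
        bundle = config.execute(cfg)
        assert bundle["converged"]
        csv_path, json_path = bundle["files"]
        assert os.path.exists(csv_path) and os.path.exists(json_path)
        meta = json.loads(open(json_path).read())
        assert meta["module"] == "edl"
        assert meta["resolved_params"]["gap_nm"] == 2.0
        assert meta["converged"] is True
        # no stray temp files from the atomic writes
        assert not [f for f in os.listdir(tmp_path / "out")
                    if f.endswith(".tmp")]

    def test_repeat_runs_byte_identical(self, tmp_path):
        blobs = []
        for run in ("a", "b"):
            cfg = config.RunConfig(**FAST_EDL,
                                   output_prefix=str(tmp_path / run))
            config.execute(cfg)
            blobs.append((open(tmp_path / f"{run}.csv", "rb").read(),
                          open(tmp_path / f"{run}.json", "rb").read()))
        assert blobs[0] == blobs[1]

    def test_failing_run_leaves_no_files(self, tmp_path):
        # invalid physical input fails during the computation; output files
        # are only written after success, so none may appear
        cfg = config.RunConfig(module="edl", task="solve",
                               params=dict(salt_molar=-0.1, sigma1=0.1,
                                           sigma2=0.0, gap_nm=2.0),
                               output_prefix=str(tmp_path / "fail"))
        with pytest.raises(ValueError):
            config.execute(cfg)
        assert not os.path.exists(tmp_path / "fail.csv")
        assert not os.path.exists(tmp_path / "fail.json")


class TestCli:
    def test_presets_list(self):
        res = CliRunner().invoke(cli.main, ["presets", "list"])
        assert res.exit_code == 0
        for name in presets.list_presets():
            assert name in res.output

    def test_edl_solve_smoke(self):
        res = CliRunner().invoke(cli.main, [
            "edl", "solve", "--sigma1", "0.05", "--sigma2", "-0.05",
            "--gap-nm", "2", "--salt-molar", "0.1", "--n-nodes", "2001",
        ])
        assert res.exit_code == 0, res.output
        summary = json.loads(res.output.splitlines()[0])
        assert summary["converged"] is True
        assert summary["Pi"] < 0.0

    def test_vesicle_minimize_smoke(self):
        res = CliRunner().invoke(cli.main, [
            "vesicle", "minimize", "--v", "0.8", "--n-modes", "20",
        ])
        assert res.exit_code == 0, res.output
        summary = json.loads(res.output.splitlines()[0])
        assert summary["shape_class"] == "prolate"

    def test_ambiguous_preset_rejected(self):
        res = CliRunner().invoke(cli.main, [
            "edl", "pressure-curve", "--preset", "fig8",
        ])
        assert res.exit_code == 2
        assert "ambiguous" in res.output

    def test_run_invalid_config_exit_2(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(dict(module="edl", task="minimize")))
        res = CliRunner().invoke(cli.main, ["run", "--config", str(path)])
        assert res.exit_code == 2

    def test_run_config_file(self, tmp_path):
        path = tmp_path / "run.yaml"
        doc = dict(FAST_EDL)
        doc["output_prefix"] = str(tmp_path / "res")
        path.write_text(yaml.safe_dump(doc))
        res = CliRunner().invoke(cli.main, ["run", "--config", str(path)])
        assert res.exit_code == 0, res.output
        assert os.path.exists(tmp_path / "res.csv")


class TestOracleTrivials:
    def test_dh_uncharged(self, water_010m):
        gap = PlanarGap.from_nm(4.0, 0.0, 0.0)
        prof = oracles.debye_huckel_oracle(gap, water_010m)
        assert np.allclose(prof.phi, 0.0)
        assert oracles.debye_huckel_pressure(gap, water_010m) == 0.0

    def test_dh_sign_conventions(self, water_010m):
        like = PlanarGap.from_nm(2.0, 0.01, 0.01)
        unlike = PlanarGap.from_nm(2.0, 0.01, -0.01)
        assert oracles.debye_huckel_pressure(like, water_010m) > 0.0
        assert oracles.debye_huckel_pressure(unlike, water_010m) < 0.0

    def test_dh_gauss_boundary(self, water_010m):
        gap = PlanarGap.from_nm(3.0, 0.01, -0.004)
        prof = oracles.debye_huckel_oracle(gap, water_010m, n_nodes=400001)
        from memadh.constants import EPS0
        eps = EPS0 * water_010m.eps_r_bulk
        dphi0 = (prof.phi[1] - prof.phi[0]) / (prof.x[1] - prof.x[0])
        dphiH = (prof.phi[-1] - prof.phi[-2]) / (prof.x[-1] - prof.x[-2])
        assert -eps * dphi0 == pytest.approx(gap.sigma1, rel=1e-4)
        assert eps * dphiH == pytest.approx(gap.sigma2, rel=1e-4)
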