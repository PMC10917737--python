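"""Cohort model, results object, config validation and end-to-end pipeline."""

import json

import numpy as np
import pytest
import yaml

from osaconnect.model import BrainConnectivityModel
from osaconnect.pipeline import RunConfig, load_config, run_pipeline
from osaconnect.synth import generate_cohort, paper_contrast_spec


@pytest.fixture(scope="module")
def small_cohort():
    spec = paper_contrast_spec(n_osa=3, n_healthy=3, duration_s=60, seed=21)
    subjects, _ = generate_cohort(spec)
    return subjects


@pytest.fixture(scope="module")
def fitted(small_cohort):
    return BrainConnectivityModel.from_cohort(small_cohort).fit()


class TestModel:
    def test_matrices_shape_and_validity(self, fitted):
        assert len(fitted.subject_ids) == 6
        for by_band in fitted.subject_matrices.values():
            assert set(by_band) == {"delta", "theta", "alpha", "beta", "gamma"}
            for m in by_band.values():
                assert m.r.shape == (4, 4)

    def test_delta_contrast_visible_in_group_summaries(self, fitted):
        tab = fitted.group_summary_table().set_index(["band", "group"])
        assert (
            tab.loc[("delta", "OSA"), "max_pos_r"]
            > tab.loc[("delta", "HEALTHY"), "max_pos_r"]
        )

    def test_subject_table_and_degree_columns(self, fitted):
        tab = fitted.subject_table()
        assert len(tab) == 6 * 5
        assert {"mean_pos_r", "n_edges", "degree_F4-A1"} <= set(tab.columns)
        # handshake lemma per row
        deg_cols = [c for c in tab.columns if c.startswith("degree_")]
        assert (tab[deg_cols].sum(axis=1) == 2 * tab["n_edges"]).all()

    def test_band_tests_and_tmaps_cover_report_bands(self, fitted):
        tests = fitted.band_tests("mean_pos_r")
        assert set(tests) == {"delta", "theta", "alpha", "beta"}
        tmaps = fitted.degree_tmaps()
        assert set(tmaps) == {"delta", "theta", "alpha", "beta"}
        for tm in tmaps.values():
            assert tm.t.shape == (4,)

    def test_summary_text_mentions_bands_and_groups(self, fitted):
        s = fitted.summary()
        for word in ("delta", "OSA", "HEALTHY", "Mann-Whitney", "db4"):
            assert word in s

    def test_group_override_mapping(self, small_cohort):
        recs = [s.recording for s in small_cohort]
        groups = {r.subject_id: "OSA" for r in recs}
        model = BrainConnectivityModel(recs, groups=groups)
        assert set(model.group_of.values()) == {"OSA"}

    def test_fit_cache_round_trip(self, small_cohort, tmp_path):
        model = BrainConnectivityModel.from_cohort(small_cohort[:2])
        r1 = model.fit(cache_dir=tmp_path, cache_key="k1")
        assert len(list(tmp_path.glob("*_k1.json"))) == 2
        r2 = model.fit(cache_dir=tmp_path, cache_key="k1")
        for sid in r1.subject_ids:
            for band in r1.subject_matrices[sid]:
                np.testing.assert_allclose(
                    r1.subject_matrices[sid][band].r,
                    r2.subject_matrices[sid][band].r,
                )


class TestRunConfig:
    def test_defaults_valid(self):
        cfg = RunConfig()
        assert cfg.wavelet.level == 5
        assert cfg.filter.notch == 50.0

    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception, match="extra"):
            RunConfig.model_validate({"no_such_key": 1})

    def test_overlapping_bands_rejected_before_io(self):
        with pytest.raises(Exception, match="overlap"):
            RunConfig.model_validate(
                {"bands": {"delta": (0.5, 5.0), "theta": (4.0, 8.0)}}
            )

    def test_missing_input_dir_rejected(self):
        with pytest.raises(Exception, match="input_dir"):
            RunConfig.model_validate({"input_kind": "columnar_dir"})

    def test_bad_group_label_rejected(self):
        with pytest.raises(Exception, match="OSA/HEALTHY"):
            RunConfig.model_validate({"group_map": {"s1": "CASE"}})

    def test_yaml_load(self, tmp_path):
        p = tmp_path / "run.yaml"
        p.write_text(yaml.safe_dump({"seed": 9, "synth": {"n_osa": 2}}))
        cfg = load_config(p)
        assert cfg.seed == 9 and cfg.synth.n_osa == 2


class TestRunPipeline:
    def _cfg(self, tmp_path, **kw):
        base = {
            "input_kind": "synth",
            "synth": {"n_osa": 2, "n_healthy": 2, "duration_s": 30.0},
            "output_dir": str(tmp_path / "out"),
            "seed": 5,
        }
        base.update(kw)
        return RunConfig.model_validate(base)

    def test_outputs_written(self, tmp_path):
        cfg = self._cfg(tmp_path)
        results = run_pipeline(cfg)
        out = tmp_path / "out"
        for name in (
            "report.json",
            "subject_table.csv",
            "group_summaries.csv",
            "band_tests.csv",
        ):
            assert (out / name).exists()
        assert list((out / "brainnet").glob("*.node"))
        assert len(list((out / "matrices").glob("*.csv"))) == 4 * 5
        rep = json.loads((out / "report.json").read_text())
        assert rep["n_subjects"] == 4
        assert not results.failures

    def test_deterministic_report(self, tmp_path):
        r1 = json.dumps(
            json.loads(
                (run_pipeline(self._cfg(tmp_path, output_dir=str(tmp_path / "a"))) or 1)
                and (tmp_path / "a" / "report.json").read_text()
            ),
            sort_keys=True,
        )
        r2 = json.dumps(
            json.loads(
                (run_pipeline(self._cfg(tmp_path, output_dir=str(tmp_path / "b"))) or 1)
                and (tmp_path / "b" / "report.json").read_text()
            ),
            sort_keys=True,
        )
        # identical modulo the differing output_dir echoed in the config
        assert r1.replace(str(tmp_path / "a"), "X") == r2.replace(
            str(tmp_path / "b"), "X"
        )

    def test_columnar_dir_input(self, tmp_path):
        spec = paper_contrast_spec(n_osa=2, n_healthy=2, duration_s=30, seed=6)
        generate_cohort(spec, out_dir=tmp_path / "cohort")
        cfg = self._cfg(
            tmp_path,
            input_kind="columnar_dir",
            input_dir=str(tmp_path / "cohort"),
        )
        results = run_pipeline(cfg)
        assert len(results.subject_ids) == 4
        assert set(results.groups_present()) == {"OSA", "HEALTHY"}

    def test_cli_end_to_end(self, tmp_path):
        from click.testing import CliRunner

        from osaconnect.cli import main

        runner = CliRunner()
        out = tmp_path / "cli_out"
        cfg = {
            "input_kind": "synth",
            "synth": {"n_osa": 2, "n_healthy": 2, "duration_s": 30.0},
            "output_dir": str(out),
            "seed": 5,
        }
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        res = runner.invoke(main, ["run", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert "Mann-Whitney" in res.output
        res2 = runner.invoke(main, ["report", "--in", str(out)])
        assert res2.exit_code == 0, res2.output
        assert "delta" in res2.output
        bad = tmp_path / "bad.yaml"
        bad.write_text("no_such_key: 1\n")
        res3 = runner.invoke(main, ["run", "--config", str(bad)])
        assert res3.exit_code == 1
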