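"""CSV dialects, config handling, metrics and the CLI pipeline."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import glvcom.io as gio
from glvcom.cli import main
from glvcom.config import ModelConfig, RunConfig, config_hash, derive_seed
from glvcom.growth import fit_dataset
from glvcom.metrics import compute_rmse_r2
from glvcom.synthetic import NoiseModel, generate_assay_dataset, sample_world

from conftest import make_iset


@pytest.fixture()
def small_assay(tmp_path):
    world = sample_world(2, seed=1)
    curves = generate_assay_dataset(world, NoiseModel(od_cv=0.02,
                                                      replicate_count=2),
                                    seed=4)
    path = tmp_path / "curves.csv"
    gio.write_growth_curves(curves, path)
    return world, curves, path


class TestGrowthCurveCsv:
    def test_round_trip_preserves_payload(self, small_assay, tmp_path):
        _world, curves, path = small_assay
        back = gio.read_growth_curves(path)
        assert len(back) == len(curves)
        # payload identical curve by curve
        key = lambda c: (c.acceptor, c.donor or "", c.replicate)
        for a, b in zip(sorted(curves, key=key), sorted(back, key=key)):
            assert key(a) == key(b)
            assert np.array_equal(a.times, b.times)
            assert np.array_equal(a.ods, b.ods)
        # and the canonical form is a fixpoint: write -> read -> write is
        # byte-identical
        p2, p3 = tmp_path / "again.csv", tmp_path / "thrice.csv"
        gio.write_growth_curves(back, p2)
        gio.write_growth_curves(gio.read_growth_curves(p2), p3)
        assert p2.read_text() == p3.read_text()

    def test_conditions_and_replicates_grouped(self, small_assay):
        _w, _c, path = small_assay
        curves = gio.read_growth_curves(path)
        conditions = {(c.acceptor, c.donor) for c in curves}
        # 2 monocultures + 2 conditioned conditions, 2 replicates each
        assert len(conditions) == 4
        assert len(curves) == 8

    def test_row_order_is_irrelevant(self, small_assay, tmp_path):
        _w, _c, path = small_assay
        df = pd.read_csv(path, float_precision="round_trip")
        shuffled = df.sample(frac=1, random_state=0)
        p2 = tmp_path / "shuffled.csv"
        shuffled.to_csv(p2, index=False)
        a = {(c.acceptor, c.donor, c.replicate): c.ods.tolist()
             for c in gio.read_growth_curves(path)}
        b = {(c.acceptor, c.donor, c.replicate): c.ods.tolist()
             for c in gio.read_growth_curves(p2)}
        assert a == b

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("acceptor,donor,time_h,od\na,,0,0.05\n")
        with pytest.raises(gio.ParseError, match="replicate"):
            gio.read_growth_curves(p)

    def test_duplicate_time_row_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("acceptor,donor,replicate,time_h,od\n"
                     "a,,r1,0,0.05\na,,r1,0,0.06\na,,r1,1,0.07\na,,r1,2,0.1\n")
        with pytest.raises(gio.ParseError, match="duplicated"):
            gio.read_growth_curves(p)

    def test_negative_od_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("acceptor,donor,replicate,time_h,od\n"
                     "a,,r1,0,0.05\na,,r1,1,-0.1\na,,r1,2,0.07\na,,r1,3,0.1\n")
        with pytest.raises(gio.ParseError, match="line 3"):
            gio.read_growth_curves(p)


class TestParamsAndInteractionsIo:
    def test_params_round_trip(self, small_assay, tmp_path):
        _w, curves, _p = small_assay
        params = fit_dataset(curves)
        path = tmp_path / "params.csv"
        gio.write_growth_params(params, path)
        back = gio.read_growth_params(path)
        assert [(p.acceptor, p.donor) for p in back] == \
            [(p.acceptor, p.donor) for p in params]
        assert np.allclose([p.final_density for p in back],
                           [p.final_density for p in params])

    def test_interaction_bundle_round_trip(self, tmp_path):
        iset = make_iset([[0.0, -0.4], [0.25, 0.0]], rates=[0.5, 0.9],
                         caps=[1.0, 1.3])
        gio.write_interactions(iset, tmp_path / "iset")
        back = gio.read_interactions(tmp_path / "iset")
        assert back.species == iset.species
        assert np.allclose(back.B, iset.B)
        assert np.allclose(back.mono_capacities, iset.mono_capacities)
        assert back.valid.dtype == bool

    def test_world_round_trip(self, tmp_path):
        world = sample_world(3, seed=5)
        gio.write_world(world, tmp_path / "w.json")
        back = gio.read_world(tmp_path / "w.json")
        assert np.array_equal(back.B, world.B)
        assert back.species == world.species


class TestConfig:
    def test_hash_changes_iff_semantic_field_changes(self):
        a = RunConfig()
        b = RunConfig()
        assert config_hash(a) == config_hash(b)
        c = RunConfig(growth_call_fold=2.5)
        assert config_hash(a) != config_hash(c)

    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(master_seed=7, model=ModelConfig(horizon_h=36.0))
        cfg.save(tmp_path / "cfg.yaml")
        back = RunConfig.load(tmp_path / "cfg.yaml")
        assert config_hash(back) == config_hash(cfg)
        assert back.model.horizon_h == 36.0

    def test_stage_seeds_distinct_and_below_2_31(self):
        seeds = {derive_seed(3, s) for s in
                 ("simulate-data", "fit-growth", "ensemble")}
        assert len(seeds) == 3
        assert all(0 <= s < 2**31 for s in seeds)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(experimental_threshold=1.5)
        with pytest.raises(ValueError):
            ModelConfig(capacity_cap=0.5)


class TestMetrics:
    def _tables(self, pairs):
        pred = pd.DataFrame([{"community": "c", "species": f"s{i}",
                              "fraction": p} for i, (p, _m) in enumerate(pairs)])
        meas = pd.DataFrame([{"community": "c", "species": f"s{i}",
                              "fraction": m} for i, (_p, m) in enumerate(pairs)])
        return pred, meas

    def test_perfect_prediction(self):
        res = compute_rmse_r2(*self._tables([(0.2, 0.2), (0.8, 0.8)]))
        assert res.rmse == 0.0 and res.r2 == pytest.approx(1.0)

    def test_hand_computed_rmse(self):
        res = compute_rmse_r2(*self._tables([(0.0, 0.2), (1.0, 0.8)]))
        assert res.rmse == pytest.approx(0.2)

    def test_anticorrelated_r2_still_in_unit_interval(self):
        res = compute_rmse_r2(*self._tables([(0.9, 0.1), (0.1, 0.9),
                                             (0.8, 0.2)]))
        assert res.r2 is not None and 0.0 <= res.r2 <= 1.0

    def test_zero_variance_side_flagged_undefined(self):
        res = compute_rmse_r2(*self._tables([(0.5, 0.2), (0.5, 0.8)]))
        assert not res.r2_defined and res.r2 is None

    def test_empty_join_rejected(self):
        pred, meas = self._tables([(0.5, 0.5)])
        meas["community"] = "other"
        with pytest.raises(ValueError):
            compute_rmse_r2(pred, meas)


class TestCli:
    def test_end_to_end_pipeline_is_reproducible(self, tmp_path):
        runner = CliRunner()
        outputs = []
        for run in ("run1", "run2"):
            d = tmp_path / run
            r = runner.invoke(main, ["simulate-data", "--n-species", "4",
                                     "--replicates", "2", "--seed", "5",
                                     "--out", str(d)])
            assert r.exit_code == 0, r.output
            r = runner.invoke(main, ["fit-growth", "--curves",
                                     str(d / "growth_curves.csv"),
                                     "--out", str(d / "params.csv")])
            assert r.exit_code == 0, r.output
            r = runner.invoke(main, ["interactions", "--params",
                                     str(d / "params.csv"),
                                     "--out", str(d / "iset")])
            assert r.exit_code == 0, r.output
            r = runner.invoke(main, ["stable-communities", "--interactions",
                                     str(d / "iset"),
                                     "--out", str(d / "communities.csv")])
            assert r.exit_code == 0, r.output
            outputs.append((d / "communities.csv").read_text())
        assert outputs[0] == outputs[1]

    def test_predict_appends_metrics_block(self, tmp_path):
        runner = CliRunner()
        d = tmp_path
        iset = make_iset(np.zeros((2, 2)), caps=[1.0, 3.0])
        gio.write_interactions(iset, d / "iset")
        measured = pd.DataFrame({
            "community": ["sp01+sp02"] * 2, "species": ["sp01", "sp02"],
            "fraction": [0.3, 0.7]})
        measured.to_csv(d / "measured.csv", index=False)
        r = runner.invoke(main, ["predict", "--interactions", str(d / "iset"),
                                 "--members", "sp01+sp02",
                                 "--measured", str(d / "measured.csv"),
                                 "--out", str(d / "pred.csv")])
        assert r.exit_code == 0, r.output
        assert (d / "pred.metrics.txt").exists()
        assert "rmse" in (d / "pred.metrics.txt").read_text()

    def test_unknown_invader_is_clean_data_error(self, tmp_path):
        runner = CliRunner()
        iset = make_iset([[0.0, -0.5], [-0.5, 0.0]])
        gio.write_interactions(iset, tmp_path / "iset")
        from glvcom.assembly import enumerate_stable_communities
        res = enumerate_stable_communities(iset)
        gio.write_community_table(res, iset.species,
                                  tmp_path / "communities.csv")
        r = runner.invoke(main, ["invade", "--interactions",
                                 str(tmp_path / "iset"),
                                 "--communities",
                                 str(tmp_path / "communities.csv"),
                                 "--invader", "nonexistent",
                                 "--out", str(tmp_path / "out.csv")])
        assert r.exit_code == 1
        r2 = runner.invoke(main, ["no-such-command"])
        assert r2.exit_code == 2

    def test_run_log_records_provenance(self, tmp_path):
        runner = CliRunner()
        d = tmp_path / "out"
        r = runner.invoke(main, ["simulate-data", "--n-species", "2",
                                 "--replicates", "1", "--seed", "1",
                                 "--out", str(d)])
        assert r.exit_code == 0, r.output
        log = (d / "run_log.txt").read_text()
        assert "config_hash=" in log and "stage_seed=" in log
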