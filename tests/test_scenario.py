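"""Scenario pipeline: coverage levels, trade-off curves, comparison tables, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from covloc import (
    CoverageMatrix,
    GeneratorParams,
    ScenarioConfig,
    ValidationError,
    build_coverage,
    enumerate_optimal,
    generate_instance,
    load_generator_params,
    load_scenario_config,
    max_achievable_fraction,
    min_facilities_for_coverage,
    plant_optimum,
    run_scenario,
    solve_greedy,
    tradeoff_curve,
    write_instance,
)
from covloc.cli import main as cli_main
from conftest import random_coverage


@pytest.fixture(scope="module")
def small_cov():
    rng = np.random.default_rng(8)
    return random_coverage(rng, n_demand=40, n_sites=10)


class TestMinFacilities:
    def test_zero_level_needs_no_facilities(self, small_cov):
        cov, h = small_cov
        assert min_facilities_for_coverage(cov, h, 0.0) == 0

    def test_monotone_in_level(self, small_cov):
        cov, h = small_cov
        cap = max_achievable_fraction(cov, h)
        levels = np.linspace(0.1, cap, 8)
        counts = [min_facilities_for_coverage(cov, h, lv) for lv in levels]
        assert counts == sorted(counts)

    def test_greedy_and_exact_agree_with_their_curves(self, small_cov):
        cov, h = small_cov
        cap = max_achievable_fraction(cov, h)
        level = 0.8 * cap
        for solver in ("greedy", "exact"):
            P = min_facilities_for_coverage(cov, h, level, solver=solver)
            curve = tradeoff_curve(cov, h, solver=solver, Pmax=P)
            assert curve.fractions[P - 1] >= level - 1e-12
            if P > 1:
                assert curve.fractions[P - 2] < level

    def test_unachievable_level_reports_maximum(self):
        a = np.array([[True], [False]])  # node 1 uncoverable
        cov = CoverageMatrix(a, 1.0, "car")
        with pytest.raises(ValidationError, match="achievable maximum"):
            min_facilities_for_coverage(cov, np.ones(2), 0.9)


class TestTradeoffCurve:
    def test_flat_at_full_coverage_when_one_site_dominates(self):
        a = np.ones((5, 3), dtype=bool)
        cov = CoverageMatrix(a, 1.0, "car")
        curve = tradeoff_curve(cov, np.ones(5), Pmax=3)
        assert curve.fractions == [1.0, 1.0, 1.0]

    def test_exact_pointwise_at_least_greedy_and_matches_enumeration(
        self, small_cov
    ):
        cov, h = small_cov
        greedy = tradeoff_curve(cov, h, solver="greedy", Pmax=5)
        exact = tradeoff_curve(cov, h, solver="exact", Pmax=5)
        for P in range(1, 6):
            opt = enumerate_optimal(cov, h, P).covered_demand
            assert exact.points[P - 1][1] == pytest.approx(opt, abs=1e-6)
            assert exact.points[P - 1][1] >= greedy.points[P - 1][1] - 1e-9

    def test_curves_non_decreasing(self, small_cov):
        cov, h = small_cov
        for solver in ("greedy", "exact"):
            vals = [p[1] for p in tradeoff_curve(cov, h, solver=solver,
                                                 Pmax=8).points]
            assert np.all(np.diff(vals) >= -1e-9)

    def test_greedy_nestedness(self, small_cov):
        """Curve point P must equal an independent greedy run at budget P."""
        cov, h = small_cov
        curve = tradeoff_curve(cov, h, Pmax=8)
        for P in range(1, 9):
            assert curve.points[P - 1][1] == pytest.approx(
                solve_greedy(cov, h, P=P).covered_demand
            )

    def test_pmax_beyond_candidates_rejected(self, small_cov):
        cov, h = small_cov
        with pytest.raises(ValidationError, match="exceeds"):
            tradeoff_curve(cov, h, Pmax=11)

    def test_frame_layout(self, small_cov):
        cov, h = small_cov
        df = tradeoff_curve(cov, h, Pmax=4).to_frame()
        assert list(df.columns) == ["P", "covered_demand", "coverage_pct"]
        assert len(df) == 4


@pytest.fixture(scope="module")
def inst():
    return generate_instance(GeneratorParams(n_demand=50, n_centres=6,
                                             seed=21))


class TestRunScenario:
    CONFIG = ScenarioConfig(
        name="pt30", candidate_selector="existing_only",
        mode="public_transport", threshold_minutes=30.0,
        solvers=("greedy", "exact", "sa"), runs=3, seed=42,
        solver_params={"sa": {"evaluations": 2000}},
    )

    def test_table_layout_and_exact_dominance(self, inst):
        table, solutions = run_scenario(inst, self.CONFIG)
        assert set(table["solver"]) == {"greedy", "exact", "sa"}
        exact_cov = table.loc[table.solver == "exact", "coverage_pct"].item()
        assert (table["coverage_pct"] <= exact_cov + 1e-9).all()
        assert table.loc[table.solver == "sa", "runs"].item() == 3
        assert len(solutions["sa"]) == 3

    def test_repeat_run_is_identical(self, inst):
        t1, _ = run_scenario(inst, self.CONFIG)
        t2, _ = run_scenario(inst, self.CONFIG)
        pd.testing.assert_frame_equal(t1.drop(columns="mean_runtime_s"),
                                      t2.drop(columns="mean_runtime_s"))

    def test_unknown_mode_lists_available(self, inst):
        cfg = ScenarioConfig(name="x", mode="bicycle")
        with pytest.raises(ValidationError, match="car"):
            run_scenario(inst, cfg)

    def test_planted_instance_recovered_exactly(self):
        pl = plant_optimum(GeneratorParams(seed=31), planted_P=3, T=10.0)
        cfg = ScenarioConfig(name="planted", candidate_selector="all",
                             mode="car", threshold_minutes=10.0,
                             solvers=("exact",), p_policy="fixed", p_value=3)
        table, solutions = run_scenario(pl.instance, cfg)
        row = table.iloc[0]
        assert row["facilities"] == pl.planted_P
        assert row["covered_demand"] == pytest.approx(pl.planted_coverage)
        assert set(solutions["exact"][0].selected) == pl.planted_sites

    def test_sweep_policy_gives_one_row_per_budget(self, inst):
        cfg = ScenarioConfig(name="sweep", mode="car", threshold_minutes=15.0,
                             solvers=("greedy",), p_policy="sweep", p_value=4)
        table, _ = run_scenario(inst, cfg)
        assert list(table["P"]) == [1, 2, 3, 4]
        assert np.all(np.diff(table["covered_demand"]) >= -1e-9)


class TestConfigFiles:
    def test_scenario_ini_roundtrip(self, tmp_path):
        ini = tmp_path / "scn.ini"
        ini.write_text(
            "[scenario]\nname = pt30\ncandidate_selector = all\n"
            "mode = public_transport\nthreshold_minutes = 30\n"
            "solvers = greedy, exact, tabu\np_policy = fixed:5\n"
            "runs = 7\nseed = 3\n\n[solver.tabu]\niterations = 50\ntenure = 3\n"
        )
        cfg = load_scenario_config(ini)
        assert cfg.solvers == ("greedy", "exact", "tabu")
        assert cfg.p_policy == "fixed" and cfg.p_value == 5
        assert cfg.runs == 7
        assert cfg.solver_params["tabu"] == {"iterations": 50, "tenure": 3}

    def test_generator_ini(self, tmp_path):
        ini = tmp_path / "gen.ini"
        ini.write_text("[generator]\nn_demand = 40\nn_centres = 4\nseed = 9\n")
        p = load_generator_params(ini)
        assert (p.n_demand, p.n_centres, p.seed) == (40, 4, 9)

    def test_bad_generator_key(self, tmp_path):
        ini = tmp_path / "gen.ini"
        ini.write_text("[generator]\nn_demands = 40\n")
        with pytest.raises(ValidationError, match="generator parameter"):
            load_generator_params(ini)


class TestCli:
    @pytest.fixture()
    def instance_files(self, tmp_path):
        inst = generate_instance(GeneratorParams(n_demand=40, n_centres=5,
                                                 seed=13))
        paths = write_instance(inst, tmp_path)
        return tmp_path, paths

    def _inst_args(self, paths):
        return [
            "--demand", str(paths["demand"]), "--sites", str(paths["sites"]),
            "--travel", f"car={paths['travel_car']}",
            "--travel", f"public_transport={paths['travel_public_transport']}",
        ]

    def test_generate_and_solve(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "gen"
        res = runner.invoke(cli_main, ["--out-dir", str(out), "--seed", "5",
                                       "generate"])
        assert res.exit_code == 0, res.output
        assert (out / "demand.csv").exists()
        paths = {"demand": out / "demand.csv", "sites": out / "sites.csv",
                 "travel_car": out / "travel_car.csv",
                 "travel_public_transport": out / "travel_public_transport.csv"}
        res = runner.invoke(
            cli_main,
            ["--out-dir", str(out), "solve", *self._inst_args(paths),
             "--mode", "car", "--threshold", "15", "--solver", "greedy"],
        )
        assert res.exit_code == 0, res.output
        report = json.loads((out / "solution_greedy.json").read_text())
        assert 0 < report["coverage_pct"] <= 100

    def test_curve_csv(self, instance_files):
        tmp_path, paths = instance_files
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["--out-dir", str(tmp_path), "curve", *self._inst_args(paths),
             "--mode", "car", "--threshold", "15", "--pmax", "5"],
        )
        assert res.exit_code == 0, res.output
        df = pd.read_csv(tmp_path / "tradeoff_greedy_car_15min.csv")
        assert list(df.columns) == ["P", "covered_demand", "coverage_pct"]
        assert len(df) == 5

    def test_scenario_command(self, instance_files):
        tmp_path, paths = instance_files
        ini = tmp_path / "scn.ini"
        ini.write_text(
            "[scenario]\nname = demo\nmode = car\nthreshold_minutes = 15\n"
            "solvers = greedy, exact\n"
        )
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["--out-dir", str(tmp_path), "scenario", *self._inst_args(paths),
             "--config", str(ini)],
        )
        assert res.exit_code == 0, res.output
        table = pd.read_csv(tmp_path / "comparison_demo.csv")
        assert set(table["solver"]) == {"greedy", "exact"}

    def test_import_s1(self, instance_files):
        tmp_path, paths = instance_files
        xlsx = tmp_path / "s1.xlsx"
        with pd.ExcelWriter(xlsx) as xl:
            pd.read_csv(paths["demand"]).to_excel(xl, sheet_name="demand", index=False)
            pd.read_csv(paths["sites"]).to_excel(xl, sheet_name="sites", index=False)
            for mode in ("car", "public_transport"):
                pd.read_csv(paths[f"travel_{mode}"]).to_excel(
                    xl, sheet_name=f"travel_{mode}", index=False
                )
        runner = CliRunner()
        out = tmp_path / "imported"
        res = runner.invoke(cli_main, ["--out-dir", str(out), "import-s1",
                                       "--xlsx", str(xlsx)])
        assert res.exit_code == 0, res.output
        from covloc import read_instance

        back = read_instance(
            out / "demand.csv", out / "sites.csv",
            {m: out / f"travel_{m}.csv" for m in ("car", "public_transport")},
        )
        assert back.n_demand == 40
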