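"""Report rendering, pipeline composition, and the command-line interface."""

import dataclasses
import json
import re
import warnings

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from infantri.cli import main as cli_main
from infantri.cohort import AnalyteSpec, CohortConfig, GroupSpec, generate_cohort
from infantri.estimators import Limit
from infantri.panel import default_analyte_specs
from infantri.pipeline import result_to_dict, run_pipeline
from infantri.report import (
    build_report,
    format_limit,
    format_median_iqr,
    render_text,
    report_to_frame,
)


class TestFormatLimit:
    def test_value_with_ci(self):
        text = format_limit(Limit(96.4), (Limit(92.1), Limit(101.6)), decimals=0)
        assert text == "96 (92–102)"

    def test_censored_with_censored_ci(self):
        cens = Limit(9.0, censored=True, loq=9.0)
        assert format_limit(cens, (cens, cens), 0) == "< 9 (< 9– < 9)"

    def test_bare_value_without_ci(self):
        assert format_limit(Limit(10.0), None, 0) == "10"

    def test_decimals_respected(self):
        assert format_limit(Limit(2.345), (Limit(2.101), Limit(2.789)), 1) == (
            "2.3 (2.1–2.8)"
        )

    def test_median_iqr(self):
        assert format_median_iqr(Limit(41.2), Limit(39.4), Limit(42.6), 0) == (
            "41 (39–43)"
        )


@pytest.fixture(scope="module")
def scaled_results():
    """Full 7-analyte grid at reduced n, fast bootstrap."""
    groups = []
    for age in (3, 6):
        for feeding, n in (("breastfed", 130), ("not_breastfed", 40)):
            groups.append(
                GroupSpec(
                    age_months=age, feeding=feeding, n=n,
                    analyte_specs=default_analyte_specs(age, feeding),
                    crp_elevated_prob=0.068,
                )
            )
    cfg = CohortConfig(groups=tuple(groups), seed=5)
    cohort = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(cohort, seed=5, boot_reps=60)
    return result_to_dict(result)


class TestBuildReport:
    def test_full_grid_shape(self, scaled_results):
        rows, footnotes = build_report(scaled_results)
        assert len(rows) == 7 * 2 * 3  # analyte x age x group column
        keys = {(r.analyte, r.age_months, r.group) for r in rows}
        assert len(keys) == 42

    def test_duplicate_series_rejected(self, scaled_results):
        doubled = dict(scaled_results)
        doubled["series"] = scaled_results["series"] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_report(doubled)

    def test_p_value_once_per_analyte_age(self, scaled_results):
        rows, _ = build_report(scaled_results)
        with_p = [r for r in rows if r.p_nutrition is not None]
        assert len(with_p) == 7 * 2
        assert all(r.group == "all" for r in with_p)

    def test_outlier_footnotes_list_cells(self, scaled_results):
        rows, footnotes = build_report(scaled_results)
        total_removed = sum(r.outliers_removed for r in rows)
        outlier_notes = [f for f in footnotes if "outlier" in f]
        if total_removed:
            assert outlier_notes
            assert all(re.match(r"\w+, \d months, \w+: \d+ outlier", f)
                       for f in outlier_notes)

    def test_n_back_reports_removed_outliers(self, scaled_results):
        rows, _ = build_report(scaled_results)
        by_key = {s["analyte"] * 0 or (s["analyte"], s["age_months"], s["group"]): s
                  for s in scaled_results["series"]}
        for r in rows:
            s = by_key[(r.analyte, r.age_months, r.group)]
            assert r.n == s["n_used"] + s["outliers_removed"]

    def test_csv_round_trips_to_printed_precision(self, scaled_results):
        rows, _ = build_report(scaled_results)
        df = report_to_frame(rows)
        assert df["median_iqr"].str.contains("–").sum() == 0  # ASCII in CSV
        by_key = {(s["analyte"], s["age_months"], s["group"]): s
                  for s in scaled_results["series"]}
        pat = re.compile(r"^(?P<v>[\d.]+|< [\d.]+) \((?P<lo>[^-]+)-(?P<hi>.+)\)$")
        for _, row in df.iterrows():
            s = by_key[(row["analyte"], row["age_months"], row["group"])]
            if s["upper_ci"] is None:
                continue
            m = pat.match(row["ul_text"])
            assert m, row["ul_text"]
            if not s["upper"]["censored"]:
                assert float(m.group("v")) == round(s["upper"]["value"], 0)

    def test_current_limits_flagging(self, scaled_results):
        current = pd.DataFrame(
            [{"analyte": "AST", "age_months": 3,
              "current_ll": 0.001, "current_ul": 50.0}]
        )
        rows, _ = build_report(scaled_results, current_limits=current)
        ast_all = next(r for r in rows
                       if (r.analyte, r.age_months, r.group) == ("AST", 3, "all"))
        # generator truth puts the 97.5th percentile far above 50 U/L
        assert ast_all.ul_outside_current is True
        assert ast_all.ll_outside_current is True
        other = next(r for r in rows if r.analyte == "Alb")
        assert other.ul_outside_current is None

    def test_render_text_contains_every_row(self, scaled_results):
        rows, footnotes = build_report(scaled_results)
        text = render_text(rows, footnotes)
        assert text.count("\n") >= len(rows)
        assert "UL (90% CI)" in text


class TestPipeline:
    def test_series_grid_and_methods(self, scaled_results):
        methods = {(s["analyte"], s["age_months"], s["group"]): s["method"]
                   for s in scaled_results["series"]}
        assert len(methods) == 42
        # pooled Alb n > 120 -> nonparametric; not-breastfed n ~ 37 -> robust
        assert methods[("Alb", 3, "all")] == "nonparametric"
        assert methods[("Alb", 3, "not_breastfed")] == "robust"
        # conjugated bilirubin is mostly below range -> direct percentiles
        assert methods[("BIL_conj", 6, "not_breastfed")] == "direct_percentile"

    def test_partition_decisions_present(self, scaled_results):
        assert "AST" in scaled_results["partitions"]
        factors = {p["factor"] for p in scaled_results["partitions"]["AST"]}
        assert factors == {"feeding", "sex"}

    def test_exclusion_counts_propagated(self, scaled_results):
        assert scaled_results["n_input"] == 2 * (130 + 40)
        frac = scaled_results["n_excluded_crp"] / scaled_results["n_input"]
        assert 0.02 < frac < 0.13

    def test_deterministic_given_seed(self, small_config):
        cohort = generate_cohort(small_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = result_to_dict(run_pipeline(cohort, seed=3, boot_reps=40))
            b = result_to_dict(run_pipeline(cohort, seed=3, boot_reps=40))
        assert a == b


class TestCli:
    def test_simulate_estimate_report_chain(self, tmp_path, small_config):
        from infantri.cohort import config_to_toml

        config_path = tmp_path / "design.toml"
        config_path.write_text(config_to_toml(small_config))
        runner = CliRunner()

        cohort_csv = tmp_path / "cohort.csv"
        r = runner.invoke(cli_main, [
            "simulate", "--config", str(config_path), "--out", str(cohort_csv)])
        assert r.exit_code == 0, r.output
        assert cohort_csv.exists()

        results_csv = tmp_path / "results.csv"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = runner.invoke(cli_main, [
                "estimate", "--input", str(cohort_csv), "--boot-reps", "50",
                "--seed", "1", "--out", str(results_csv)])
        assert r.exit_code == 0, r.output
        results_json = tmp_path / "results.json"
        assert results_csv.exists() and results_json.exists()
        df = pd.read_csv(results_csv)
        assert {"analyte", "method", "LL", "UL"} <= set(df.columns)

        report_txt = tmp_path / "report.txt"
        r = runner.invoke(cli_main, [
            "report", "--results", str(results_json), "--out", str(report_txt),
            "--csv", str(tmp_path / "report.csv")])
        assert r.exit_code == 0, r.output
        assert "ALT" in report_txt.read_text()

    def test_simulate_seed_override_changes_cohort(self, tmp_path, small_config):
        from infantri.cohort import config_to_toml

        config_path = tmp_path / "design.toml"
        config_path.write_text(config_to_toml(small_config))
        runner = CliRunner()
        out1, out2 = tmp_path / "c1.csv", tmp_path / "c2.csv"
        runner.invoke(cli_main, ["simulate", "--config", str(config_path),
                                 "--out", str(out1)])
        runner.invoke(cli_main, ["simulate", "--config", str(config_path),
                                 "--seed", "99", "--out", str(out2)])
        assert out1.read_text() != out2.read_text()
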