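"""Tests of the experiment layer: accuracy, grids, loci and MAF studies."""

import numpy as np
import pandas as pd
import pytest

from nipthmm.classify import ChromosomeCall
from nipthmm.evaluate import (
    AccuracyReport,
    GridConfig,
    accuracy,
    loci_subsample_experiment,
    maf_informative_experiment,
    run_grid,
    theoretical_informative_fraction,
)
from nipthmm.simulate import EUPLOIDY, MATERNAL_TRISOMY, PATERNAL_TRISOMY


class TestAccuracy:
    def test_examples(self):
        assert accuracy(["a", "b"], ["a", "b"]) == 1.0
        assert accuracy(["unclassified"] * 3, ["a", "b", "c"]) == 0.0
        assert accuracy(["a", "a", "b", "b"], ["a", "a", "b", "c"]) == 0.75

    def test_accepts_chromosome_calls(self):
        calls = [ChromosomeCall("euploidy", "mode"), ChromosomeCall("trisomy", "mode")]
        assert accuracy(calls, ["euploidy", "euploidy"]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])


class TestInformativeFractions:
    @pytest.mark.parametrize(
        "condition,expected",
        [(EUPLOIDY, 0.75), (MATERNAL_TRISOMY, 0.75), (PATERNAL_TRISOMY, 0.875)],
    )
    def test_maf_half_closed_forms(self, condition, expected):
        assert theoretical_informative_fraction(0.5, condition) == expected

    def test_monomorphic_limit(self):
        for cond in (EUPLOIDY, MATERNAL_TRISOMY, PATERNAL_TRISOMY):
            assert theoretical_informative_fraction(0.0, cond) == 0.0

    def test_simulation_matches_theory_within_two_points(self):
        df = maf_informative_experiment(
            maf_set=(0.05, 0.20, 0.50), n_variants=1000, n_reps=100, seed=3
        )
        assert (np.abs(df["simulated"] - df["theoretical"]) <= 0.02).all()

    def test_fraction_decreases_with_maf(self):
        df = maf_informative_experiment(
            maf_set=(0.01, 0.10, 0.50), n_variants=500, n_reps=50, seed=4
        )
        for _, grp in df.groupby("condition"):
            sim = grp.sort_values("maf")["simulated"].to_numpy()
            assert (np.diff(sim) > 0).all()


@pytest.fixture(scope="module")
def tiny_grid_report():
    cfg = GridConfig(
        ff_values=(0.16,),
        rd_values=(2000,),
        n_loci=300,
        n_train=40,
        n_test=30,
        seed=9,
    )
    return run_grid(cfg)


class TestRunGrid:
    def test_single_cell_layout(self, tiny_grid_report):
        cells = tiny_grid_report.cells
        assert set(cells["model"]) == {"RC_fixed", "AR", "RCAR"}
        assert set(cells["method"]) == {"mode", "tree", "margin"}
        assert cells["accuracy"].between(0, 1).all()
        # one cell per (model, method, condition)
        assert len(cells) == 3 * 3 * 3

    def test_high_ff_rd_cell_is_accurate(self, tiny_grid_report):
        # at FF 16%, RD 2000 every model/method detects euploidy and
        # maternal trisomy nearly perfectly
        df = tiny_grid_report.subset(condition=MATERNAL_TRISOMY, method="margin")
        assert (df["accuracy"] >= 0.9).all()

    def test_overall_equals_cell_mean(self, tiny_grid_report):
        df = tiny_grid_report.subset(model="RC_fixed", method="mode")
        assert tiny_grid_report.overall("RC_fixed", "mode") == pytest.approx(
            df["accuracy"].mean()
        )

    def test_report_round_trip(self, tiny_grid_report, tmp_path):
        path = tmp_path / "cells.tsv"
        tiny_grid_report.to_tsv(path)
        clone = AccuracyReport.from_tsv(path)
        pd.testing.assert_frame_equal(clone.cells, tiny_grid_report.cells)

    def test_unknown_model_kind_rejected(self):
        with pytest.raises(ValueError, match="model kinds"):
            GridConfig(model_kinds=("RC_fixed", "XX"))


class TestAggregation:
    def _report(self):
        rows = []
        for ff, acc in [(0.02, 0.4), (0.04, 0.6), (0.12, 0.9), (0.20, 1.0)]:
            rows.append(
                {
                    "model": "RC_fixed",
                    "method": "mode",
                    "condition": EUPLOIDY,
                    "ff": ff,
                    "rd": 1000,
                    "accuracy": acc,
                    "n": 10,
                }
            )
        return AccuracyReport(cells=pd.DataFrame(rows))

    def test_band_and_overall_aggregates(self):
        rep = self._report()
        assert rep.band("RC_fixed", "mode", (0.01, 0.05)) == pytest.approx(0.5)
        assert rep.band("RC_fixed", "mode", (0.11, 0.15)) == pytest.approx(0.9)
        assert rep.overall("RC_fixed", "mode") == pytest.approx(0.725)

    def test_band_table_shape(self):
        table = self._report().band_table()
        assert list(table.index) == ["1-5%", "6-10%", "11-15%", "16-20%", "total"]


class TestLociSubsampling:
    def test_tiny_experiment_layout_and_bounds(self):
        rep = loci_subsample_experiment(
            n_loci_set=(20, 60),
            rd=1000,
            ff_set=(0.10,),
            n_loci_full=60,
            n_train=30,
            n_test=20,
            seed=5,
        )
        cells = rep.cells
        assert set(cells["n_loci"]) == {20, 60}
        assert set(cells["method"]) == {"mode", "tree", "margin"}
        assert cells["accuracy"].between(0, 1).all()

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError, match="subsample"):
            loci_subsample_experiment(n_loci_set=(2000,), n_loci_full=1000)
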