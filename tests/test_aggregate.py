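"""Result-table aggregation, imputation, and the accuracy predictor."""

import numpy as np
import pandas as pd
import pytest

from spikeval import (
    AggregationParams,
    StudyResultTable,
    average_metric,
    count_above,
    fit_accuracy_predictor,
    impute_missing,
)


def make_table(snr_acc_by_cell: dict, missing=(), study_sets=None) -> StudyResultTable:
    """cells: {(sorter, study, recording): [(snr, accuracy), ...]}"""
    rows = []
    study_sets = study_sets or {}
    for (sorter, study, rec), units in snr_acc_by_cell.items():
        for i, (snr, acc) in enumerate(units):
            rows.append(
                dict(
                    sorter=sorter,
                    study_set=study_sets.get(study, "SS"),
                    study=study,
                    recording=rec,
                    gt_unit=i + 1,
                    accuracy=acc,
                    precision=acc,
                    recall=acc,
                    snr=snr,
                    num_events=100,
                )
            )
    return StudyResultTable(units=pd.DataFrame(rows), missing=set(missing))


class TestAverageMetric:
    def test_snr_threshold_excludes_subthreshold_units(self):
        table = make_table({("S", "st", "r"): [(9, 0.9), (10, 0.7), (3, 0.1)]})
        study, _ = average_metric(table, AggregationParams(snr_threshold=8))
        assert study.loc["S", "st"] == pytest.approx(0.8)

    def test_zero_threshold_averages_all_units(self):
        table = make_table({("S", "st", "r"): [(9, 0.9), (10, 0.7), (3, 0.1)]})
        study, _ = average_metric(table, AggregationParams(snr_threshold=0))
        assert study.loc["S", "st"] == pytest.approx((0.9 + 0.7 + 0.1) / 3)

    def test_study_set_is_mean_of_study_means(self):
        table = make_table(
            {
                ("S", "st1", "r1"): [(9, 0.6), (9, 0.6)],
                ("S", "st2", "r2"): [(9, 0.8)],
            }
        )
        study, study_set = average_metric(table, AggregationParams())
        assert study_set.loc["S", "SS"] == pytest.approx(0.7)

    def test_no_qualifying_units_flagged_empty(self):
        table = make_table({("S", "st", "r"): [(3, 0.9)]})
        study, _ = average_metric(table, AggregationParams(snr_threshold=8))
        assert np.isnan(study.loc["S", "st"])

    def test_impute_noop_on_complete_table(self):
        cells = {
            ("A", "st", "r1"): [(9, 0.8)],
            ("A", "st", "r2"): [(9, 0.6)],
            ("B", "st", "r1"): [(9, 0.5)],
            ("B", "st", "r2"): [(9, 0.7)],
        }
        with_imp, _ = average_metric(make_table(cells), AggregationParams(impute=True))
        without, _ = average_metric(make_table(cells), AggregationParams(impute=False))
        pd.testing.assert_frame_equal(with_imp, without)

    def test_missing_recording_imputed_from_complete_sorter(self):
        # B = 0.5*A + 0.1 exactly on observed recordings
        a_vals = [0.2, 0.4, 0.6, 0.8]
        cells = {}
        for i, v in enumerate(a_vals):
            cells[("A", "st", f"r{i}")] = [(9, v)]
            if i != 3:
                cells[("B", "st", f"r{i}")] = [(9, 0.5 * v + 0.1)]
        table = make_table(cells, missing={("B", "r3")})
        study, _ = average_metric(table, AggregationParams())
        expected_b = np.mean([0.5 * v + 0.1 for v in a_vals])
        assert study.loc["B", "st"] == pytest.approx(expected_b, abs=1e-8)

    def test_raising_snr_threshold_never_adds_units(self):
        rng = np.random.default_rng(3)
        units = [(s, a) for s, a in zip(rng.uniform(0, 20, 30), rng.uniform(0, 1, 30))]
        table = make_table({("S", "st", "r"): units})
        qualifying = [
            np.count_nonzero(table.units["snr"] >= thr) for thr in (0, 5, 10, 15)
        ]
        assert qualifying == sorted(qualifying, reverse=True)


class TestCountAbove:
    def test_threshold_count(self):
        table = make_table({("S", "st", "r"): [(9, 0.85), (9, 0.79), (9, 0.90)]})
        counts, flags = count_above(table, AggregationParams(accuracy_threshold=0.8))
        assert counts.loc["S", "st"] == 2
        assert not flags.loc["S", "st"]

    def test_counts_ignore_snr(self):
        table = make_table({("S", "st", "r"): [(0.5, 0.95)]})
        counts, _ = count_above(table, AggregationParams())
        assert counts.loc["S", "st"] == 1

    def test_missing_never_imputed_and_flagged(self):
        cells = {
            ("A", "st", "r1"): [(9, 0.9)],
            ("A", "st", "r2"): [(9, 0.9)],
            ("B", "st", "r1"): [(9, 0.9)],
        }
        table = make_table(cells, missing={("B", "r2")})
        counts, flags = count_above(table, AggregationParams())
        assert counts.loc["B", "st"] == 1  # only the non-missing unit
        assert flags.loc["B", "st"]
        assert not flags.loc["A", "st"]

    def test_raising_threshold_never_increases_count(self):
        rng = np.random.default_rng(4)
        table = make_table(
            {("S", "st", "r"): [(9, a) for a in rng.uniform(0, 1, 50)]}
        )
        counts = [
            count_above(table, AggregationParams(accuracy_threshold=t))[0].loc["S", "st"]
            for t in (0.0, 0.3, 0.6, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestImputeMissing:
    def _linear_pair(self, rng, n=10, holes=(2, 5, 7)):
        a = rng.uniform(0.2, 0.9, n)
        b = 0.5 * a + 0.1
        cols = [f"r{i}" for i in range(n)]
        vals = pd.DataFrame([a, b], index=["A", "B"], columns=cols)
        mask = pd.DataFrame(False, index=vals.index, columns=cols)
        truth = vals.loc["B"].copy()
        for h in holes:
            mask.loc["B", cols[h]] = True
            vals.loc["B", cols[h]] = np.nan
        return vals, mask, truth

    def test_exact_linear_dependence_recovered(self, rng):
        vals, mask, truth = self._linear_pair(rng)
        filled = impute_missing(vals, mask)
        assert np.abs(filled.loc["B"] - truth).max() < 1e-8

    def test_observed_entries_untouched(self, rng):
        vals, mask, _ = self._linear_pair(rng)
        observed = vals.loc["B"].copy()
        filled = impute_missing(vals, mask)
        kept = ~mask.loc["B"]
        assert (filled.loc["B"][kept] == observed[kept]).all()

    def test_predictions_clipped_to_unit_interval(self):
        vals = pd.DataFrame(
            [[0.1, 0.5, 0.9, 0.95], [0.9, 1.0, 1.0, np.nan]],
            index=["A", "B"],
            columns=list("wxyz"),
        )
        mask = pd.DataFrame(False, index=vals.index, columns=vals.columns)
        mask.loc["B", "z"] = True
        filled = impute_missing(vals, mask)
        assert 0.0 <= filled.loc["B", "z"] <= 1.0

    def test_underdetermined_falls_back_to_observed_mean(self):
        vals = pd.DataFrame(
            [[0.4, 0.6, 0.8], [0.5, np.nan, np.nan]],
            index=["A", "B"],
            columns=list("xyz"),
        )
        mask = pd.DataFrame(False, index=vals.index, columns=vals.columns)
        mask.loc["B", ["y", "z"]] = True
        filled = impute_missing(vals, mask)
        # one observed entry cannot support intercept + slope: mean fallback
        assert filled.loc["B", "y"] == pytest.approx(0.5)
        assert filled.loc["B", "z"] == pytest.approx(0.5)

    def test_no_complete_sorter_falls_back(self):
        vals = pd.DataFrame(
            [[0.4, np.nan], [np.nan, 0.6]], index=["A", "B"], columns=["x", "y"]
        )
        mask = pd.DataFrame(
            [[False, True], [True, False]], index=["A", "B"], columns=["x", "y"]
        )
        filled = impute_missing(vals, mask)
        assert filled.loc["A", "y"] == pytest.approx(0.4)
        assert filled.loc["B", "x"] == pytest.approx(0.6)


class TestAccuracyPredictor:
    def _units(self, rng, n=60):
        return pd.DataFrame(
            dict(
                snr=rng.uniform(2, 20, n),
                firing_rate=rng.uniform(0.5, 30, n),
                isi_violation_ratio=rng.uniform(0.01, 3, n),
            )
        )

    def test_exact_linear_model_recovered(self, rng):
        units = self._units(rng)
        units["accuracy"] = (
            0.3
            + 0.02 * units["snr"]
            + 0.005 * units["firing_rate"]
            + 0.04 * np.log(units["isi_violation_ratio"])
        )
        fit = fit_accuracy_predictor(units)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert fit.coefficients["snr"] == pytest.approx(0.02, abs=1e-9)
        assert fit.coefficients["firing_rate"] == pytest.approx(0.005, abs=1e-9)
        assert fit.coefficients["log_isi_vr"] == pytest.approx(0.04, abs=1e-9)

    def test_pure_noise_has_low_correlation(self):
        rng = np.random.default_rng(99)
        units = self._units(rng, n=2000)
        units["accuracy"] = rng.uniform(0, 1, len(units))
        fit = fit_accuracy_predictor(units)
        assert abs(fit.pearson_r) < 0.12

    def test_multi_predictor_beats_single_predictors(self, rng):
        units = self._units(rng, n=200)
        units["accuracy"] = np.clip(
            0.4 + 0.02 * units["snr"] + rng.normal(0, 0.1, len(units)), 0, 1
        )
        fit = fit_accuracy_predictor(units)
        for col in ("snr", "firing_rate"):
            single = abs(np.corrcoef(units[col], units["accuracy"])[0, 1])
            assert fit.pearson_r >= single - 1e-9

    def test_collinear_predictor_dropped(self, rng):
        units = self._units(rng)
        units["firing_rate"] = 2.0 * units["snr"] + 1.0  # exactly collinear
        units["accuracy"] = 0.3 + 0.02 * units["snr"]
        fit = fit_accuracy_predictor(units)
        assert len(fit.dropped) == 1
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-6)

    def test_zero_isi_floored_for_log(self, rng):
        units = self._units(rng, n=20)
        units.loc[0, "isi_violation_ratio"] = 0.0
        units["accuracy"] = rng.uniform(0, 1, len(units))
        fit = fit_accuracy_predictor(units)  # must not raise or produce NaN
        assert np.all(np.isfinite(fit.predictions))

    def test_too_few_units_rejected(self, rng):
        units = self._units(rng, n=4)
        units["accuracy"] = 0.5
        with pytest.raises(ValueError, match="at least 5"):
            fit_accuracy_predictor(units)
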