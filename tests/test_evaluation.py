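import math

import numpy as np
import pytest

from oolemma.evaluation import (
    AggregationError,
    ConfusionMatrix,
    GridCell,
    PipelineConfig,
    aggregate_by_dimensionality,
    aggregate_by_frames,
    best_cell,
    cells_frame,
    chi_square_test,
    count_feature_instances,
    extract_features,
    grid_search,
    leave_one_oocyte_out,
    metrics,
    raw_metrics,
    round_half_up,
    write_reports,
)


class TestMetrics:
    @pytest.mark.parametrize("cm, expected", [
        (ConfusionMatrix(tp=3, fn=1, tn=4, fp=2), (70.00, 75.00, 66.67)),
        (ConfusionMatrix(tp=5, tn=5), (100.00, 100.00, 100.00)),
        (ConfusionMatrix(tp=0, fn=4, tn=6, fp=0), (60.00, 0.00, 100.00)),
    ])
    def test_percentage_definitions(self, cm, expected):
        assert metrics(cm) == expected

    def test_zero_denominator_yields_nan_marker(self):
        acc, sens, spec = metrics(ConfusionMatrix(tn=5, fp=1))
        assert math.isnan(sens) and not math.isnan(acc) and not math.isnan(spec)

    def test_round_half_up_convention(self):
        assert round_half_up(82.445) == 82.45
        assert round_half_up(0.125) == 0.13
        assert round_half_up(-2.935) == -2.94


class TestChiSquare:
    def test_perfect_association(self):
        stat, p = chi_square_test(ConfusionMatrix(tp=20, tn=20))
        assert stat == pytest.approx(40.0)
        assert p < 1e-9

    def test_independence(self):
        stat, p = chi_square_test(ConfusionMatrix(tp=10, fn=10, fp=10, tn=10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_threshold_at_3p841_for_significance(self):
        # any 2x2 statistic above the 95th-percentile chi-square quantile
        # (1 df) has p < 0.05
        cm = ConfusionMatrix(tp=15, fn=5, fp=7, tn=13)
        stat, p = chi_square_test(cm)
        assert (stat > 3.841) == (p < 0.05)

    def test_zero_margin_undefined(self):
        stat, p = chi_square_test(ConfusionMatrix(tp=5, fn=5))
        assert math.isnan(stat) and math.isnan(p)


class TestBookkeeping:
    def test_feature_instance_enumerator(self):
        assert count_feature_instances(93) == 5115
        assert count_feature_instances(93, [1, 2, 3], [1]) == 279

    def test_grid_cell_count(self, small_cohort):
        cells = grid_search(small_cohort, [1, 2], [1, 2, 3], ["linear", "rbf"])
        assert len(cells) == 2 * 2 * 3
        per_kernel = [c for c in cells if c.kernel == "rbf"]
        assert len(per_kernel) == 6

    def test_confusion_totals_scale_with_frames(self, small_cohort):
        for n in (1, 2):
            cm = leave_one_oocyte_out(small_cohort, n, 2, "linear")
            assert cm.total == len(small_cohort) * n
            n_rup = sum(s.label == "ruptured" for s in small_cohort)
            assert cm.tp + cm.fn == n_rup * n

    def test_metric_identities_hold_for_every_cell(self, small_cohort):
        cells = grid_search(small_cohort, [1, 2], [1, 2], ["polynomial"])
        for c in cells:
            cm = c.confusion
            assert c.accuracy == pytest.approx(100 * (cm.tp + cm.tn) / cm.total)
            acc, sens, spec = raw_metrics(cm)
            assert (c.sensitivity == pytest.approx(sens)
                    if not math.isnan(sens) else math.isnan(c.sensitivity))

    def test_grid_matches_single_cell_evaluation(self, small_cohort):
        cells = grid_search(small_cohort, [1, 2], [1, 2, 3], ["rbf"])
        target = next(c for c in cells
                      if c.n_samples == 2 and c.dimensionality == 3)
        single = leave_one_oocyte_out(small_cohort, 2, 3, "rbf")
        assert target.confusion == single


class TestCrossValidation:
    def test_minimal_two_oocyte_cv(self, small_cohort):
        pair = [next(s for s in small_cohort if s.label == "ruptured"),
                next(s for s in small_cohort if s.label == "nonruptured")]
        cm = leave_one_oocyte_out(pair, 1, 1, "linear")
        assert cm.total == 2

    def test_single_class_dataset_rejected(self, small_cohort):
        rup = [s for s in small_cohort if s.label == "ruptured"]
        with pytest.raises(ValueError):
            leave_one_oocyte_out(rup, 1, 1, "linear")

    def test_folds_never_share_an_oocyte(self, small_cohort):
        folds = []
        grid_search(small_cohort, [1, 2], [1, 2], ["linear"],
                    fold_hook=lambda tr, te: folds.append((tr, te)))
        assert folds
        for train_ids, test_ids in folds:
            assert not train_ids & test_ids
            assert len(test_ids) == 1

    def test_every_oocyte_held_out_once_per_pass(self, small_cohort):
        held = []
        leave_one_oocyte_out(small_cohort, 1, 2, "linear",
                             fold_hook=lambda tr, te: held.extend(te))
        assert sorted(held) == sorted(s.oocyte_id for s in small_cohort)

    def test_extract_features_shapes(self, small_cohort):
        X, y, groups = extract_features(small_cohort, 3)
        assert X.shape == (len(small_cohort) * 3, 256)
        assert set(y) == {-1, 1}
        assert len(set(groups)) == len(small_cohort)


def _fake_cells(values_by_group, kernel="polynomial", group="n_samples"):
    cells = []
    for g, vals in values_by_group.items():
        for d, v in enumerate(vals, start=1):
            kw = dict(n_samples=g, dimensionality=d) if group == "n_samples" \
                else dict(n_samples=d, dimensionality=g)
            cells.append(GridCell(kernel=kernel, confusion=None, accuracy=v,
                                  sensitivity=math.nan, specificity=math.nan, **kw))
    return cells


class TestAggregation:
    def test_mean_sd_match_independent_routine(self):
        rng = np.random.default_rng(3)
        vals = {g: list(rng.uniform(50, 95, size=11)) for g in (1, 2, 3)}
        rows = aggregate_by_frames(_fake_cells(vals))
        for row in rows:
            v = np.array(vals[row.group_key])
            assert row.mean["polynomial"] == pytest.approx(v.mean(), abs=1e-9)
            assert row.sd["polynomial"] == pytest.approx(v.std(ddof=1), abs=1e-9)

    def test_change_is_difference_of_unrounded_means(self):
        vals = {1: [60.0] * 3, 2: [60.004, 60.004, 60.004]}
        rows = aggregate_by_frames(_fake_cells(vals))
        assert rows[0].change["polynomial"] is None
        assert rows[1].change["polynomial"] == pytest.approx(0.004)
        # displayed: change rounds from the unrounded difference
        assert round_half_up(rows[1].change["polynomial"]) == 0.00

    def test_identical_groups_have_zero_sd_and_change(self):
        vals = {1: [70.0] * 11, 2: [70.0] * 11}
        rows = aggregate_by_frames(_fake_cells(vals))
        assert rows[1].sd["polynomial"] == 0.0
        assert rows[1].change["polynomial"] == 0.0

    def test_dimensionality_grouping(self):
        vals = {d: [50.0 + d] * 5 for d in (1, 2)}
        rows = aggregate_by_dimensionality(_fake_cells(vals, group="dimensionality"))
        assert [r.group_key for r in rows] == [1, 2]
        assert rows[1].change["polynomial"] == pytest.approx(1.0)

    def test_incomplete_grid_reports_missing_cells(self):
        cells = _fake_cells({1: [60.0] * 11, 2: [60.0] * 10})
        with pytest.raises(AggregationError, match="missing"):
            aggregate_by_frames(cells)


class TestReports:
    def test_report_files_written(self, small_cohort, tmp_path):
        cells = grid_search(small_cohort, [1, 2], [1, 2], ["linear", "rbf"])
        paths = write_reports(cells, tmp_path, seed=0)
        for key in ("table1", "table2", "table3", "log"):
            assert paths[key].exists()
        df = cells_frame(cells)
        assert len(df) == len(cells)
        assert {"TP", "TN", "FP", "FN", "accuracy"} <= set(df.columns)
        assert len(list((tmp_path / "confusion").glob("*.csv"))) == len(cells)

    def test_best_cell_selection(self):
        cells = _fake_cells({1: [10.0, 90.0, 50.0]})
        b = best_cell(cells)
        assert b.accuracy == 90.0 and b.dimensionality == 2
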