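"""Confusion-count conventions, derived metrics, and the area benchmark."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from hippomorph.evaluation import (
    ConfusionCounts,
    area_benchmark,
    class_metrics,
    cohen_kappa,
    confusion_from_predictions,
    counts_from_row,
    load_reference_counts,
    metrics_report,
    overall_metrics,
    polygon_area,
)
from hippomorph.io import Cohort, ContourReading

from conftest import circle_points


class TestConfusionFromPredictions:
    def test_mirror_convention_on_worked_example(self):
        # 30 controls all correct; 33 subjects with one called control
        truth = ["control"] * 30 + ["subject"] * 33
        predicted = ["control"] * 30 + ["subject"] * 32 + ["control"]
        c = confusion_from_predictions(truth, predicted)
        assert (c.tp_c, c.tp_s, c.tn_c, c.tn_s) == (30, 32, 30, 32)
        assert (c.fp_c, c.fp_s, c.fn_c, c.fn_s) == (1, 0, 0, 1)

    def test_all_correct_has_no_errors(self):
        truth = ["control"] * 5 + ["subject"] * 5
        c = confusion_from_predictions(truth, truth)
        assert c.fp_c == c.fp_s == c.fn_c == c.fn_s == 0
        assert c.n_correct == 10

    def test_degenerate_predictor(self):
        truth = ["control"] * 7 + ["subject"] * 3
        predicted = ["subject"] * 10
        c = confusion_from_predictions(truth, predicted)
        assert c.tp_c == 0 and c.fn_c == 7 and c.fp_s == 7

    def test_standard_convention_differs(self):
        truth = ["control"] * 4 + ["subject"] * 6
        predicted = ["control"] * 3 + ["subject"] * 7
        mirrored = confusion_from_predictions(truth, predicted)
        standard = confusion_from_predictions(truth, predicted, convention="standard")
        assert mirrored.tn_c == mirrored.tp_c == 3
        assert standard.tn_c == standard.tp_s == 6

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            confusion_from_predictions(["control"], ["case"])


class TestClassMetrics:
    def test_published_three_mode_row(self):
        c = ConfusionCounts(29, 31, 29, 31, 2, 1, 1, 2, 30, 33)
        m = class_metrics(c, "C")
        assert m["precision"] == pytest.approx(29 / 31, abs=1e-12)
        assert m["accuracy"] == pytest.approx(58 / 61, abs=1e-12)

    def test_published_seven_mode_row(self):
        c = ConfusionCounts(29, 33, 29, 33, 0, 1, 1, 0, 30, 33)
        m = class_metrics(c, "C")
        assert m["specificity"] == 1.0
        assert m["f_measure"] == pytest.approx(0.983, abs=5e-4)

    def test_perfect_counts_give_unit_metrics(self):
        c = ConfusionCounts(30, 33, 30, 33, 0, 0, 0, 0, 30, 33)
        for view in ("C", "S"):
            assert all(v == 1.0 for v in class_metrics(c, view).values())

    def test_negative_counts_rejected(self):
        c = ConfusionCounts(-1, 0, 0, 0, 0, 0, 1, 0, 0, 0)
        with pytest.raises(ValueError, match="negative"):
            class_metrics(c, "C")

    def test_degenerate_ratio_warns(self):
        c = ConfusionCounts(0, 3, 0, 3, 0, 0, 0, 0, 0, 3)
        with pytest.warns(UserWarning, match="0/0"):
            class_metrics(c, "C")


class TestOverallMetrics:
    def test_published_kappa_left_and_right(self):
        left = confusion_from_predictions(
            ["control"] * 30 + ["subject"] * 33,
            ["control"] * 29 + ["subject"] + ["control"] * 2 + ["subject"] * 31,
        )
        assert cohen_kappa(left) == pytest.approx(0.9047, abs=5e-5)
        right = confusion_from_predictions(
            ["control"] * 30 + ["subject"] * 33,
            ["control"] * 30 + ["control"] + ["subject"] * 32,
        )
        assert cohen_kappa(right) == pytest.approx(0.9682, abs=5e-5)

    def test_zero_one_loss_identities(self):
        c = ConfusionCounts(29, 31, 29, 31, 2, 1, 1, 2, 30, 33)
        m = overall_metrics(c)
        assert m["mae"] == pytest.approx(1 - m["percent_correct"] / 100, abs=1e-12)
        assert m["rmse"] == pytest.approx(np.sqrt(m["mae"]), abs=1e-12)
        assert m["mae"] == pytest.approx(3 / 63, abs=1e-12)
        assert m["rmse"] == pytest.approx(0.2182, abs=5e-5)

    def test_kappa_is_one_iff_no_errors(self):
        perfect = ConfusionCounts(30, 33, 30, 33, 0, 0, 0, 0, 30, 33)
        assert cohen_kappa(perfect) == 1.0
        imperfect = ConfusionCounts(29, 33, 29, 33, 0, 1, 1, 0, 30, 33)
        assert cohen_kappa(imperfect) < 1.0

    def test_random_predictions_give_near_zero_kappa(self):
        rng = np.random.default_rng(0)
        n = 10_000
        truth = np.where(rng.random(n) < 0.5, "control", "subject")
        predicted = np.where(rng.random(n) < 0.5, "control", "subject")
        c = confusion_from_predictions(truth, predicted)
        assert abs(cohen_kappa(c)) < 0.05

    def test_kappa_bounds_random_configurations(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            truth = np.where(rng.random(40) < 0.5, "control", "subject")
            predicted = np.where(rng.random(40) < 0.5, "control", "subject")
            if len(set(truth)) < 2:
                continue
            k = cohen_kappa(confusion_from_predictions(truth, predicted))
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12

    def test_report_reproduces_reference_table_spot_rows(self):
        table = load_reference_counts()
        row = table[(table.side == "left") & (table.modes == 3)].iloc[0]
        m = metrics_report(counts_from_row(row))
        assert m.overall["percent_correct"] == pytest.approx(95.2381, abs=5e-5)
        assert m.overall["kappa"] == pytest.approx(0.9047, abs=5e-5)


class TestPolygonArea:
    def test_unit_square(self):
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert polygon_area(sq) == pytest.approx(1.0, abs=1e-15)

    @given(
        st.lists(st.floats(0.5, 5.0), min_size=4, max_size=30),
        st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_shoelace_oracle_on_star_polygons(self, radii, phase_int):
        n = len(radii)
        th = 2 * np.pi * (np.arange(n) + phase_int / 10_001) / n
        pts = np.array(radii)[:, None] * np.column_stack([np.cos(th), np.sin(th)])
        shoelace = Polygon(pts).area
        assert polygon_area(pts) == pytest.approx(shoelace, abs=1e-12 * max(1, shoelace))

    def test_orientation_independent(self):
        pts = circle_points(9, radius=2.0)
        assert polygon_area(pts) == pytest.approx(polygon_area(pts[::-1]), abs=1e-12)

    def test_open_or_tiny_contour_rejected(self):
        with pytest.raises(ValueError, match="closed contour"):
            polygon_area(np.zeros((2, 2)))


def square_reading(subject, group, area, side="left"):
    half = np.sqrt(area) / 2
    pts = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
    return ContourReading(
        subject_id=subject,
        side=side,
        group=group,
        reader_id="r1",
        repeat_index=0,
        points=pts,
        fiducial_indices=(0,),
    )


class TestAreaBenchmark:
    def test_reading_areas_averaged_per_subject(self):
        readings = [
            square_reading("s1", "control", 4.0),
            square_reading("s1", "control", 16.0),
            square_reading("s2", "subject", 9.0),
        ]
        readings[1].repeat_index = 1
        bench = area_benchmark(Cohort(readings=readings).validate())
        s1 = bench.areas[bench.areas.subject_id == "s1"].iloc[0]
        assert s1.area == pytest.approx(10.0, abs=1e-9)

    def test_identical_group_distributions_overlap_half(self):
        rng = np.random.default_rng(2)
        readings = []
        for i in range(30):
            readings.append(square_reading(f"c{i}", "control", rng.normal(100, 10)))
        for i in range(33):
            readings.append(square_reading(f"s{i}", "subject", rng.normal(100, 10)))
        bench = area_benchmark(Cohort(readings=readings).validate())
        overlap = bench.overlap_counts["left"]
        # null case: the likelihood-ratio rule misclassifies about half,
        # within the binomial 95% band around 31.5 of 63
        assert 23 <= overlap <= 40

    def test_separated_groups_have_few_ambiguities(self):
        rng = np.random.default_rng(3)
        readings = []
        for i in range(30):
            readings.append(square_reading(f"c{i}", "control", rng.normal(140, 8)))
        for i in range(33):
            readings.append(square_reading(f"s{i}", "subject", rng.normal(100, 8)))
        bench = area_benchmark(Cohort(readings=readings).validate())
        assert bench.overlap_counts["left"] <= 6
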