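import math

import numpy as np
import pytest

from segadapt.adaptation import (
    AdaptationResult,
    ExplicitQuality,
    FeatureQuality,
    GridError,
    ParameterGrid,
    adapt_per_image,
    adapt_robust,
    best_of,
    case1_experiment,
    delta_sweep,
    evaluate_fixed,
)
from segadapt.evaluation import FuzzySpec, robustness_R
from segadapt.pipeline import ParameterVector, run_pipeline


def _criterion(gt):
    return ExplicitQuality(gt.labels, gt.class_map)


class TestParameterGrid:
    def test_from_bounds_values(self):
        grid = ParameterGrid.from_bounds(0.1, 0.2, 0.05)
        assert grid.t_values == (0.1, 0.15, 0.2)

    def test_invalid_bounds(self):
        with pytest.raises(GridError):
            ParameterGrid.from_bounds(0.5, 0.4, 0.01)

    def test_delta_out_of_range(self):
        with pytest.raises(GridError):
            ParameterGrid.from_bounds(0.1, 0.3, 0.25)
        with pytest.raises(GridError):
            ParameterGrid.from_bounds(0.1, 0.3, 0.0)

    def test_empty_dimension_rejected(self):
        with pytest.raises(GridError):
            ParameterGrid(w_values=(), t_values=(0.5,), s_values=(1,))

    def test_nested_grids_share_values(self):
        fine = set(ParameterGrid.from_bounds(0.1, 0.74, 0.02).t_values)
        for delta in (0.04, 0.08, 0.16):
            coarse = set(ParameterGrid.from_bounds(0.1, 0.74, delta).t_values)
            assert coarse <= fine

    def test_row_major_order_and_len(self):
        grid = ParameterGrid(w_values=(1, 3), t_values=(0.1, 0.2), s_values=(1,))
        pts = grid.points()
        assert len(grid) == len(pts) == 4
        assert [(p.w, p.t) for p in pts] == [(1, 0.1), (1, 0.2), (3, 0.1), (3, 0.2)]


class TestAdaptPerImage:
    def test_single_point_grid(self, tiny_scene):
        _, image, gt = tiny_scene
        grid = ParameterGrid(t_values=(0.5,))
        res = adapt_per_image(image, "manual_threshold", grid, _criterion(gt))
        assert res.params == ParameterVector(1, 0.5, 1)
        assert len(res.trace) == 1

    def test_clean_scene_perfect_quality_in_gap(self, two_level_scene):
        _, image, gt = two_level_scene
        grid = ParameterGrid.from_bounds(0.1, 0.78, 0.02)
        res = adapt_per_image(image, "manual_threshold", grid, _criterion(gt))
        assert res.score == 1.0
        # strict ">" threshold: t equal to the background level is perfect
        assert 0.2 <= res.params.t < 0.8

    def test_bit_identical_to_bruteforce(self, tiny_scene):
        # independent exhaustive double loop over the same 20-point grid
        _, image, gt = tiny_scene
        crit = _criterion(gt)
        grid = ParameterGrid(
            w_values=(1, 3), t_values=(0.2, 0.3, 0.4, 0.5, 0.6), s_values=(1, 3)
        )
        res = adapt_per_image(image, "manual_threshold", grid, crit)
        best_score, best_p = -1.0, None
        for w in (1, 3):
            for t in (0.2, 0.3, 0.4, 0.5, 0.6):
                for s in (1, 3):
                    p = ParameterVector(w, t, s)
                    v = crit.score(run_pipeline(image, p, "manual_threshold"))
                    if v > best_score or (
                        v == best_score and (t, w, s) < (best_p.t, best_p.w, best_p.s)
                    ):
                        best_score, best_p = v, p
        assert res.score == best_score
        assert res.params == best_p

    def test_score_is_max_of_trace(self, tiny_scene):
        _, image, gt = tiny_scene
        grid = ParameterGrid.from_bounds(0.1, 0.7, 0.1)
        res = adapt_per_image(image, "manual_threshold", grid, _criterion(gt))
        assert res.score == max(v for _, v in res.trace)

    def test_tie_breaks_to_smallest_t(self, two_level_scene):
        _, image, gt = two_level_scene
        # every t in (0.2, 0.8) is perfect; the smallest must win
        grid = ParameterGrid(t_values=(0.3, 0.4, 0.5))
        res = adapt_per_image(image, "manual_threshold", grid, _criterion(gt))
        assert res.score == 1.0
        assert res.params.t == 0.3

    def test_superset_dominance(self, tiny_series):
        crit = _criterion(tiny_series.ground_truth)
        small = ParameterGrid(t_values=(0.3, 0.5))
        big = ParameterGrid(t_values=(0.2, 0.3, 0.4, 0.5, 0.6), s_values=(1, 3))
        for img in tiny_series.images:
            r_small = adapt_per_image(img, "manual_threshold", small, crit)
            r_big = adapt_per_image(img, "manual_threshold", big, crit)
            assert r_big.score >= r_small.score

    def test_feature_criterion(self, two_level_scene):
        _, image, _ = two_level_scene
        spec = FuzzySpec(feature_edges={"area": (50.0, 100.0, 130.0, 150.0)})
        grid = ParameterGrid.from_bounds(0.3, 0.7, 0.1)
        res = adapt_per_image(image, "manual_threshold", grid, FeatureQuality(spec))
        assert 0.0 <= res.score <= 1.0
        assert res.criterion == "Q_feat"


class TestAdaptRobust:
    def test_single_point_grid(self, tiny_series):
        crit = _criterion(tiny_series.ground_truth)
        grid = ParameterGrid(t_values=(0.4,))
        res = adapt_robust(tiny_series, "manual_threshold", grid, crit)
        assert res.params.t == 0.4

    def test_identical_images_reduce_to_per_image(self, two_level_scene):
        _, image, gt = two_level_scene
        crit = _criterion(gt)
        grid = ParameterGrid.from_bounds(0.1, 0.7, 0.05)
        rob = adapt_robust([image, image, image], "manual_threshold", grid, crit)
        per = adapt_per_image(image, "manual_threshold", grid, crit)
        assert rob.params == per.params
        assert rob.score == per.score

    def test_bit_identical_to_bruteforce(self, tiny_series):
        crit = _criterion(tiny_series.ground_truth)
        ts = (0.2, 0.3, 0.4, 0.5, 0.6)
        grid = ParameterGrid(w_values=(1,), t_values=ts, s_values=(1, 3, 5, 7))
        res = adapt_robust(tiny_series, "manual_threshold", grid, crit)
        best_r, best_p = -1.0, None
        for t in ts:
            for s in (1, 3, 5, 7):
                p = ParameterVector(1, t, s)
                qs = [
                    crit.score(run_pipeline(img, p, "manual_threshold"))
                    for img in tiny_series.images
                ]
                r = math.fsum(qs) / len(qs)
                if r > best_r or (
                    r == best_r and (t, 1, s) < (best_p.t, best_p.w, best_p.s)
                ):
                    best_r, best_p = r, p
        assert res.score == best_r
        assert res.params == best_p

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            adapt_robust([], "otsu", ParameterGrid(), ExplicitQuality(np.zeros((4, 4))))


class TestBestOf:
    def _res(self, score, criterion="Q", label="x"):
        p = ParameterVector()
        return AdaptationResult(p, score, ((p, score),), "otsu", criterion, label)

    def test_feedback_wins_when_higher(self):
        assert best_of(self._res(0.3, label="std"), self._res(0.7)).score == 0.7

    def test_tie_goes_to_feedback(self):
        fb = self._res(0.5, label="auto")
        assert best_of(self._res(0.5, label="std"), fb) is fb

    def test_never_below_feedforward(self, tiny_series):
        crit = _criterion(tiny_series.ground_truth)
        grid = ParameterGrid(t_values=(0.9,))  # deliberately bad grid
        for img in tiny_series.images:
            std = evaluate_fixed(img, ParameterVector(1, 0.4, 1), "manual_threshold", crit)
            auto = adapt_per_image(img, "manual_threshold", grid, crit)
            assert best_of(std, auto).score >= std.score

    def test_criterion_mismatch_rejected(self):
        with pytest.raises(ValueError):
            best_of(self._res(0.5, criterion="Q"), self._res(0.5, criterion="Q_feat"))

    def test_pointwise_max_over_series(self, tiny_series):
        crit = _criterion(tiny_series.ground_truth)
        grid = ParameterGrid.from_bounds(0.2, 0.6, 0.1)
        for img in tiny_series.images:
            std = evaluate_fixed(img, ParameterVector(1, 0.5, 1), "manual_threshold", crit)
            auto = adapt_per_image(img, "manual_threshold", grid, crit)
            assert best_of(std, auto).score == max(std.score, auto.score)


class TestDeltaSweep:
    def test_single_delta_single_row(self, tiny_series):
        crit = _criterion(tiny_series.ground_truth)
        table = delta_sweep(tiny_series, "manual_threshold", [0.1], 0.2, 0.6, crit)
        assert len(table) == 1
        assert set(table.columns) >= {"delta", "R"}

    def test_nested_deltas_non_increasing(self, tiny_series):
        crit = _criterion(tiny_series.ground_truth)
        table = delta_sweep(
            tiny_series, "manual_threshold", [0.05, 0.1, 0.2], 0.2, 0.6, crit
        )
        r = table["R"].to_numpy()
        assert np.all(np.diff(r) <= 1e-15)


class TestCase1Experiment:
    def test_schema_and_orderings(self, tiny_series):
        out = case1_experiment(tiny_series)
        table = out["table"]
        assert list(table["b"]) == [1, 2, 3]
        for tag in ("otsu", "edge"):
            assert (table[f"Q_auto_{tag}"] >= table[f"Q_std_{tag}"] - 1e-15).all()
            assert out["robustness"][f"R_auto_{tag}"] >= out["robustness"][f"R_std_{tag}"] - 1e-15
        # robustness values are the means of the per-level columns
        for name, value in out["robustness"].items():
            col = name.replace("R_", "Q_")
            assert value == pytest.approx(robustness_R(table[col].tolist()))
        assert "Q_multi_auto" in table.columns

    def test_clean_only_series_near_perfect(self, two_level_scene):
        from segadapt.benchmark import generate_series

        spec, _, _ = two_level_scene
        series = generate_series(spec, B=1, N=14, sigma_max=0.02, shading_max=0.0)
        out = case1_experiment(series, include_multi=False)
        table = out["table"]
        assert table["Q_auto_otsu"].iloc[0] > 0.95
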