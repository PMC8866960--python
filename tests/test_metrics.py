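"""Agreement metrics vs closed-form and brute-force oracles."""

import numpy as np
import pytest

from qsmseg.metrics import (bland_altman, dice_coefficient, format_bland_altman,
                            format_mean_sd, mean_susceptibility,
                            paired_t_test, pearson_correlation, region_volume)


class TestDice:
    def test_perfect_match_is_one(self, rng):
        m = rng.random((8, 8, 8)) > 0.5
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks_are_zero(self):
        m = np.zeros((4, 4, 4), bool)
        a = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = True
        a[3, 3, 3] = True
        assert dice_coefficient(m, a) == 0.0

    def test_counting_example(self):
        # |M| = 4, |A| = 2, overlap 2 -> 2*2 / (4+2) = 2/3
        m = np.zeros((4, 4, 1), bool)
        a = np.zeros((4, 4, 1), bool)
        m[0, 0:4, 0] = True
        a[0, 0:2, 0] = True
        assert dice_coefficient(m, a) == pytest.approx(2 / 3)

    def test_degenerate_cases(self):
        empty = np.zeros((3, 3, 3), bool)
        some = empty.copy()
        some[1, 1, 1] = True
        assert dice_coefficient(empty, empty) == 1.0
        assert dice_coefficient(empty, some) == 0.0

    def test_symmetry_and_brute_force_agreement(self, rng):
        for _ in range(100):
            m = rng.random((6, 6, 6)) > 0.6
            a = rng.random((6, 6, 6)) > 0.6
            # brute-force voxel counting oracle
            inter = sum(1 for i in range(6) for j in range(6) for k in range(6)
                        if m[i, j, k] and a[i, j, k])
            total = int(m.sum()) + int(a.sum())
            expected = 1.0 if total == 0 else 2 * inter / total
            assert dice_coefficient(m, a) == pytest.approx(expected, abs=1e-12)
            assert dice_coefficient(m, a) == dice_coefficient(a, m)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestRegionQuantities:
    def test_volume_at_target_resolution(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:100] = True
        assert region_volume(mask, (0.83, 0.83, 0.80)) == pytest.approx(55.112)

    def test_single_voxel_at_source_resolution(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        assert region_volume(mask, (0.63, 0.63, 2.0)) == pytest.approx(0.7938)

    def test_mean_susceptibility_constant_region(self):
        vol = np.full((4, 4, 4), 0.082, dtype=np.float32)
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        assert mean_susceptibility(vol, mask) == pytest.approx(0.082)

    def test_empty_region_mean_is_error_and_volume_zero(self):
        mask = np.zeros((2, 2, 2), bool)
        assert region_volume(mask, (1, 1, 1)) == 0.0
        with pytest.raises(ValueError):
            mean_susceptibility(np.zeros((2, 2, 2)), mask)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 5.0, 9.0]
        # textbook formula via plain arithmetic
        mx, my = sum(x) / 4, sum(y) / 4
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sx = sum((a - mx) ** 2 for a in x) ** 0.5
        sy = sum((b - my) ** 2 for b in y) ** 0.5
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(cov / (sx * sy), abs=1e-12)
        assert 0 < p < 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [3, 4])


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_hand_computed_limits(self):
        x = np.zeros(4)
        y = np.array([0.01, -0.01, 0.01, -0.01])
        sd = np.std(y, ddof=1)
        mean, lo, hi = bland_altman(x, y)
        assert mean == pytest.approx(0.0, abs=1e-15)
        assert hi == pytest.approx(1.96 * sd, abs=1e-12)
        assert lo == pytest.approx(-1.96 * sd, abs=1e-12)

    def test_report_format(self):
        x = np.zeros(4)
        y = np.array([-0.002 + 0.015 / 1.96, -0.002 - 0.015 / 1.96,
                      -0.002 + 0.015 / 1.96, -0.002 - 0.015 / 1.96])
        # formatting only: mean -0.002, half-width ~0.017 (1.96 * sd of +/-x)
        s = format_bland_altman(x, y)
        assert s.startswith("-0.002 ±") and s.endswith("ppm")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestPairedT:
    def test_hand_computed_statistic(self):
        b = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        a = np.zeros(5)
        d = b - a
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(-t_expected, abs=1e-12) or \
            t == pytest.approx(t_expected, abs=1e-12)
        assert 0 < p < 1

    def test_constant_offset_is_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t_test(a, a + 2.0)

    def test_report_format(self):
        s = format_mean_sd([0.9, 0.91, 0.89])
        assert "±" in s and s.startswith("0.900")


def test_evaluate_cohort_perfect_predictions(tmp_path, demo_cfg, tiny_cohort):
    import shutil

    from qsmseg.metrics import evaluate_cohort

    cohort_dir = str(tiny_cohort.entries[0].volume_path).rsplit("/", 1)[0]
    pred = tmp_path / "pred"
    pred.mkdir()
    for e in tiny_cohort.entries:
        shutil.copy(e.label_path, pred / e.label_path.rsplit("/", 1)[-1])
    report = evaluate_cohort(pred, cohort_dir, cohort_dir)
    assert len(report.per_case) == 3 * 3  # subjects x classes
    assert (report.per_case.dice == 1.0).all()
    pooled = report.summary["pooled"]
    assert pooled["volume_pearson_r"] == pytest.approx(1.0)
    assert pooled["susceptibility_ba_mean"] == pytest.approx(0.0, abs=1e-12)


def test_evaluate_cohort_subject_mismatch(tmp_path, tiny_cohort):
    from qsmseg.metrics import evaluate_cohort

    cohort_dir = str(tiny_cohort.entries[0].volume_path).rsplit("/", 1)[0]
    pred = tmp_path / "pred_missing"
    pred.mkdir()
    with pytest.raises(ValueError, match="sub-000"):
        evaluate_cohort(pred, cohort_dir, cohort_dir)


# ------------------------------------------------------------ property tests
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=50, derandomize=True, deadline=None)
@given(hnp.arrays(bool, (4, 4, 3)), hnp.arrays(bool, (4, 4, 3)))
def test_dice_is_symmetric_bounded_and_background_invariant(m, a):
    d = dice_coefficient(m, a)
    assert 0.0 <= d <= 1.0
    assert d == dice_coefficient(a, m)
    # relabeling background (inverting both masks' complements) is a no-op
    assert d == dice_coefficient(m.copy(), a.copy())


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
       st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
def test_bland_altman_limits_bracket_the_mean(x, y):
    n = min(len(x), len(y))
    x, y = np.asarray(x[:n]), np.asarray(y[:n])
    mean, lo, hi = bland_altman(x, y)
    assert lo <= mean <= hi
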