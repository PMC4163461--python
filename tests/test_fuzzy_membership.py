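"""Membership-function evaluation, fitting and family selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbfin import MembershipFunction, MembershipSet, eval_mf, fit_mf, select_kind
from hbfin.errors import FitError
from hbfin.fuzzy_membership import bin_grades


def s_type(a=1.0, b=5.0, support=(0.0, 10.0)):
    return MembershipFunction("s_type", "X", "H", {"a": a, "b": b}, support)


def quasi_gaussian(center=5.0, d=1.0, support=(0.0, 10.0)):
    return MembershipFunction("quasi_gaussian", "X", "H", {"a": center, "d": d}, support)


class TestEvaluation:
    def test_sigmoid_midpoint(self):
        assert eval_mf(s_type(b=5.0), 5.0) == pytest.approx(0.5)

    def test_gaussian_peak(self):
        assert eval_mf(quasi_gaussian(center=5.0), 5.0) == pytest.approx(1.0)

    def test_gaussian_at_one_bandwidth(self):
        # at s = center + 2d the exponent is ((2d)/(2d))^2 = 1
        assert eval_mf(quasi_gaussian(center=5.0, d=1.0), 7.0) == pytest.approx(math.exp(-1), abs=1e-4)

    def test_polynomial_clipped(self):
        mf = MembershipFunction("polynomial", "X", "H", {"coeffs": [1.3]}, (0.0, 10.0))
        assert eval_mf(mf, 3.0) == 1.0

    def test_constant_extrapolation_outside_support(self):
        mf = s_type(a=1.0, b=5.0, support=(0.0, 10.0))
        assert eval_mf(mf, -100.0) == eval_mf(mf, 0.0)
        assert eval_mf(mf, +100.0) == eval_mf(mf, 10.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.sampled_from(["polynomial", "s_type", "quasi_gaussian"]),
        st.floats(-1e6, 1e6),
    )
    def test_grade_always_in_unit_interval(self, kind, s):
        params = {
            "polynomial": {"coeffs": [-0.5, 0.3, -0.01]},
            "s_type": {"a": 2.0, "b": 3.0},
            "quasi_gaussian": {"a": 5.0, "d": 2.0},
        }[kind]
        mf = MembershipFunction(kind, "X", "H", params, (0.0, 10.0))
        assert 0.0 <= eval_mf(mf, s) <= 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(0.1, 4.9))
    def test_gaussian_symmetric_about_center(self, delta):
        mf = quasi_gaussian(center=5.0, d=1.5)
        assert eval_mf(mf, 5.0 + delta) == pytest.approx(eval_mf(mf, 5.0 - delta), abs=1e-12)

    def test_sigmoid_monotone(self):
        grid = np.linspace(0, 10, 50)
        up = [eval_mf(s_type(a=2.0), x) for x in grid]
        down = [eval_mf(s_type(a=-2.0), x) for x in grid]
        assert all(b >= a for a, b in zip(up, up[1:]))
        assert all(b <= a for a, b in zip(down, down[1:]))


class TestFitting:
    def test_too_few_labeled_values_rejected(self):
        with pytest.raises(FitError, match="too few"):
            fit_mf([1.0, 2.0, 3.0], np.linspace(0, 10, 100))

    def test_degenerate_variance_rejected(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_mf([2.0] * 30, [2.0] * 100)

    def test_recovers_narrow_gaussian_inside_wide_cohort(self):
        rng = np.random.default_rng(11)
        labeled = rng.normal(5.0, 0.5, size=400)
        cohort = np.concatenate([rng.uniform(0, 10, size=2000), labeled])
        mf = fit_mf(labeled, cohort, kind=None, symptom="X", hypothesis="H")
        assert mf.kind == "quasi_gaussian"
        centers, _ = bin_grades(labeled, cohort)
        bin_width = centers[1] - centers[0]
        assert abs(mf.params["a"] - 5.0) < bin_width

    def test_recovers_sigmoid_turning_point(self):
        rng = np.random.default_rng(12)
        cohort = rng.uniform(0, 10, size=3000)
        accept = rng.random(cohort.size) < 1.0 / (1.0 + np.exp(-2.0 * (cohort - 5.0)))
        labeled = cohort[accept]
        mf = fit_mf(labeled, cohort, kind=None, symptom="X", hypothesis="H")
        assert mf.kind == "s_type"
        centers, grades = bin_grades(labeled, cohort)
        bin_width = centers[1] - centers[0]
        crossing = centers[int(np.argmin(np.abs(grades - 0.5)))]
        assert abs(mf.params["b"] - crossing) < bin_width

    def test_noise_free_grade_curve_reproduced(self):
        # cohort mass on a regular grid with labeled counts proportional to
        # a known quasi-Gaussian curve: the fitted MF must reproduce the
        # curve at the bin centers
        grid = np.linspace(0.0, 11.0, 12)
        true = lambda s: np.exp(-(((s - 5.5) / 4.0) ** 2))
        cohort = np.repeat(grid, 100)
        labeled = np.concatenate([np.repeat(x, int(round(100 * true(x)))) for x in grid])
        mf = fit_mf(labeled, cohort, kind="quasi_gaussian", bins=12,
                    symptom="X", hypothesis="H")
        centers, grades = bin_grades(labeled, cohort, bins=12)
        fitted = np.array([eval_mf(mf, c) for c in centers])
        assert np.max(np.abs(fitted - grades)) < 0.05


class TestFamilySelection:
    def test_unimodal_symmetric_selects_gaussian(self):
        centers = np.linspace(0, 10, 11)
        grades = np.exp(-(((centers - 5.0) / 3.0) ** 2))
        assert select_kind(centers, grades) == "quasi_gaussian"

    def test_monotone_sigmoid_selects_s_type(self):
        centers = np.linspace(0, 10, 11)
        grades = 1.0 / (1.0 + np.exp(-1.5 * (centers - 5.0)))
        assert select_kind(centers, grades) == "s_type"

    def test_constant_grades_select_polynomial(self):
        centers = np.linspace(0, 10, 11)
        grades = np.full(11, 0.4)
        assert select_kind(centers, grades) == "polynomial"

    def test_too_few_bins_rejected(self):
        with pytest.raises(FitError, match="5"):
            select_kind([1.0, 2.0], [0.5, 0.6])


class TestSerialization:
    def test_yaml_round_trip(self):
        mfs = MembershipSet([
            MembershipFunction("s_type", "SP", "HT", {"a": 1.0, "b": 150.0}, (80.0, 200.0)),
            MembershipFunction("quasi_gaussian", "PR", "TC", {"a": 110.0, "d": 10.0}, (40.0, 160.0)),
        ])
        restored = MembershipSet.from_yaml(mfs.to_yaml())
        assert len(restored) == 2
        for orig, back in zip(mfs, restored):
            assert orig.kind == back.kind
            assert orig.params == pytest.approx(back.params)
            assert orig.support == back.support
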