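"""Agreement statistics against independently computed textbook values."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from cervcobb import (
    LandmarkSet,
    OutlierFence,
    ValidationError,
    bland_altman,
    build_report,
    icc_two_way,
    mae,
    paired_t_test,
    pck,
    pearson,
)
from cervcobb.agreement import AgreementReport, ba_plot_table
from cervcobb.volume_io import LANDMARK_NAMES

# Fixed 6-pair worked set.  The expected values below were computed from the
# two-way ANOVA table / textbook formulas by the oracle in
# test_icc_matches_anova_oracle and frozen here.
X6 = np.array([10.0, 12.5, 8.0, 15.0, 11.0, 9.5])
Y6 = np.array([11.0, 12.0, 9.5, 14.0, 12.5, 9.0])


def anova_icc_oracle(x, y):
    """ICC(2,1) from first principles: mean squares of the two-way table."""
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    absolute = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    consistency = (msr - mse) / (msr + (k - 1) * mse)
    return absolute, consistency


def _lm_pair(case, jitter):
    pts = {n: np.array([10.0 * i, 5.0]) for i, n in enumerate(LANDMARK_NAMES)}
    ref = LandmarkSet(case_id=case, reader_id="ref", points=pts)
    moved = {n: p + jitter for n, p in pts.items()}
    pred = LandmarkSet(case_id=case, reader_id="pred", points=moved)
    return pred, ref


class TestWorkedSet:
    """Every metric reproduces the independently computed value to 1e-9."""

    def test_icc_matches_anova_oracle(self):
        expected, _ = anova_icc_oracle(X6, Y6)
        assert expected == pytest.approx(0.878048780487805, abs=1e-12)
        assert icc_two_way(X6, Y6).value == pytest.approx(expected, abs=1e-9)

    def test_absolute_agreement_penalizes_bias(self):
        shifted = Y6 + 10.0
        absolute, consistency = anova_icc_oracle(X6, shifted)
        assert icc_two_way(X6, shifted).value == pytest.approx(absolute, abs=1e-9)
        assert absolute < consistency

    def test_pearson_value(self):
        assert pearson(X6, Y6).r == pytest.approx(0.9004365418992263, abs=1e-9)

    def test_mae_value(self):
        assert mae(X6, Y6).value == pytest.approx(1.0, abs=1e-12)

    def test_bland_altman_values(self):
        res = bland_altman(X6, Y6)
        assert res.mean_diff == pytest.approx(-1.0 / 3.0, abs=1e-12)
        assert res.sd_diff == pytest.approx(1.1254628677422756, abs=1e-9)
        assert res.loa[0] == pytest.approx(-2.5392405541081935, abs=1e-9)
        assert res.loa[1] == pytest.approx(1.8725738874415268, abs=1e-9)

    def test_paired_t_value(self):
        res = paired_t_test(X6, Y6)
        assert res.t == pytest.approx(-0.7254762501100115, abs=1e-9)
        assert res.significant is False


class TestPairedT:
    def test_identical_lists(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_swap_negates_t(self):
        a = paired_t_test(X6, Y6)
        b = paired_t_test(Y6, X6)
        assert a.t == pytest.approx(-b.t, abs=1e-12)

    def test_alternating_differences_hand_value(self):
        x = np.array([1.0, 0.0, 3.0, 2.0])
        y = x - np.array([1.0, -1.0, 1.0, -1.0])
        res = paired_t_test(x, y)  # mean diff 0 -> t = 0
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_constant_nonzero_differences_flagged(self):
        res = paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert np.isnan(res.t) and res.significant is None
        assert "zero-variance" in res.note


class TestPearson:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.band == "extremely strong"

    def test_negative_slope(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        res = pearson(x, -x)
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert res.band == "extremely strong"  # band uses |r|

    def test_permutation_destroys_correlation(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=2000)
        y = x[rng.permutation(2000)]
        assert abs(pearson(x, y).r) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestICC:
    def test_perfect_agreement(self):
        res = icc_two_way([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.value == 1.0
        assert res.ci95 == (1.0, 1.0)
        assert res.band == "excellent"

    def test_band_cut_points(self):
        from cervcobb.agreement import _icc_band

        assert _icc_band(0.39) == "poor"
        assert _icc_band(0.4) == "general"
        assert _icc_band(0.6) == "good"
        assert _icc_band(0.75) == "excellent"

    def test_insufficient_n(self):
        with pytest.raises(ValidationError):
            icc_two_way([1.0, 2.0], [1.0, 2.0])


class TestMAE:
    def test_hand_example(self):
        assert mae([1.0, 2.0], [2.0, 4.0]).value == pytest.approx(1.5)

    def test_symmetric_in_arguments(self):
        assert mae(X6, Y6).value == mae(Y6, X6).value

    def test_bootstrap_ci_brackets_value_and_is_seeded(self):
        a = mae(X6, Y6, seed=1)
        b = mae(X6, Y6, seed=1)
        assert a == b
        assert a.ci95[0] <= a.value <= a.ci95[1]


class TestBlandAltman:
    def test_identity(self):
        res = bland_altman(X6, X6)
        assert res.mean_diff == 0.0 and res.sd_diff == 0.0 and res.loa == (0.0, 0.0)

    def test_hand_example_n_minus_one_sd(self):
        res = bland_altman([1.0, 0.0], [0.0, 1.0])  # differences [1, -1]
        assert res.sd_diff == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert res.loa[1] == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-9)

    def test_translation_equivariance(self):
        base = bland_altman(X6, Y6)
        shifted = bland_altman(X6 + 3.5, Y6)
        assert shifted.mean_diff == pytest.approx(base.mean_diff + 3.5, abs=1e-12)
        assert shifted.loa[0] == pytest.approx(base.loa[0] + 3.5, abs=1e-12)
        assert shifted.loa[1] == pytest.approx(base.loa[1] + 3.5, abs=1e-12)


class TestPCK:
    def _sets(self, offsets):
        pred, ref = [], []
        for i, off in enumerate(offsets):
            p, r = _lm_pair(f"c{i}", np.array([off, 0.0]))
            pred.append(p)
            ref.append(r)
        return pred, ref

    def test_identity_is_hundred_percent(self):
        pred, ref = self._sets([0.0, 0.0, 0.0])
        fence = OutlierFence(per_landmark_tp_mm={n: 2.8 for n in LANDMARK_NAMES})
        assert all(v == 1.0 for v in pck(pred, ref, fence).values())

    def test_counting_and_strict_boundary(self):
        # offsets 1, 2, 2.8, 4 against Tp = 2.8: exactly-at-fence is incorrect
        pred, ref = self._sets([1.0, 2.0, 2.8, 4.0])
        fence = OutlierFence(per_landmark_tp_mm={n: 2.8 for n in LANDMARK_NAMES})
        assert pck(pred, ref, fence)["C2_ant"] == pytest.approx(0.5)
        wider = OutlierFence(per_landmark_tp_mm={n: 2.8001 for n in LANDMARK_NAMES})
        assert pck(pred, ref, wider)["C2_ant"] == pytest.approx(0.75)

    def test_non_decreasing_in_fence(self):
        rng = np.random.default_rng(7)
        pred, ref = self._sets(rng.normal(0, 1.5, size=30))
        prev = 0.0
        for tp in np.linspace(0.1, 5.0, 25):
            fence = OutlierFence(per_landmark_tp_mm={n: float(tp) for n in LANDMARK_NAMES})
            frac = pck(pred, ref, fence)["C2_ant"]
            assert frac >= prev
            prev = frac


class TestBuildReport:
    def test_self_comparison_identities(self):
        angles = [3.0, -5.0, 12.0, 0.5, 8.0, -2.0]
        pred, ref = [], []
        for i in range(6):
            p, r = _lm_pair(f"c{i}", np.array([0.0, 0.0]))
            pred.append(p)
            ref.append(r)
        fence = OutlierFence(per_landmark_tp_mm={n: 2.8 for n in LANDMARK_NAMES})
        report, ba = build_report(pred, ref, angles, angles, fence)
        assert all(v == 1.0 for v in report.pck_per_landmark.values())
        assert report.icc.value == 1.0
        assert report.pearson_r.r == pytest.approx(1.0, abs=1e-12)
        assert report.mae_deg.value == 0.0
        assert report.bland_altman.loa == (0.0, 0.0)
        assert np.all(ba["difference"] == 0.0)

    def test_json_round_trip(self, tmp_path):
        fence = OutlierFence(per_landmark_tp_mm={n: 2.8 for n in LANDMARK_NAMES})
        pred, ref = [], []
        for i in range(6):
            p, r = _lm_pair(f"c{i}", np.array([0.5, 0.0]))
            pred.append(p)
            ref.append(r)
        report, _ = build_report(pred, ref, X6, Y6, fence, seed=3)
        path = report.to_json(tmp_path / "rep.json")
        back = AgreementReport.from_json(path)
        assert back == report

    def test_plot_table_mean_and_difference(self):
        tab = ba_plot_table([2.0, 4.0], [1.0, 2.0])
        np.testing.assert_allclose(tab["mean"], [1.5, 3.0])
        np.testing.assert_allclose(tab["difference"], [1.0, 2.0])


class TestJitterTrend:
    def test_icc_degrades_with_corner_jitter(self):
        """Line-fitting-vs-truth ICC falls as reader jitter grows (seeded)."""
        from cervcobb import generate_case, measure_line_fitting, select_midsagittal
        from cervcobb.phantom import cohort_specs

        levels = [0.2, 0.5, 0.8, 1.2, 1.5]
        base = cohort_specs(12, 42, endplate_curvature=0.02)
        iccs = []
        for j, lev in enumerate(levels):
            truths, ests = [], []
            for i, sp in enumerate(base):
                sp2 = replace(sp, corner_jitter_sd_mm=lev, rng_seed=sp.rng_seed + 1000 * j)
                case = generate_case(sp2, f"c{i}")
                _, slc = select_midsagittal(case.volume)
                ests.append(measure_line_fitting(slc, case.reader_landmarks[0]).angle_deg)
                truths.append(case.truth_cobb_deg)
            iccs.append(icc_two_way(ests, truths).value)
        rho = spearmanr(levels, iccs).statistic
        assert rho < 0.0
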