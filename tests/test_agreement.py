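"""Reliability and validity statistics battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cmjkin.agreement import (DegenerateTableError, MeasurementTable,
                              PowerQuery, ba_from_summary, bland_altman,
                              build_tables, cv_percent, hinkle_magnitude,
                              icc_3_1, mean_difference, pearson_graded,
                              sample_size_correlation, sem_abs)
from conftest import oracle_icc31


def table(rows):
    return MeasurementTable(np.asarray(rows, float))


class TestICC31:
    def test_constant_offset_gives_one(self):
        # consistency form: a per-method shift is not disagreement
        icc, lo, hi = icc_3_1(table([(1, 2), (2, 3), (3, 4)]))
        assert icc == 1.0 == lo == hi

    def test_duplicated_column_gives_one(self):
        icc, _, _ = icc_3_1(table([(1, 1), (4, 4), (9, 9)]))
        assert icc == 1.0

    def test_hand_anova_reference_table(self):
        # frozen value from the explicit sums-of-squares oracle:
        # MS_S = 18.1, MS_E = 0.5 → ICC = 17.6/18.6
        icc, lo, hi = icc_3_1(table([(1, 2), (4, 3), (5, 6), (8, 7), (9, 9)]))
        assert icc == pytest.approx(0.946236559139785, abs=1e-12)
        assert lo == pytest.approx(0.5806296927882587, abs=1e-9)
        assert hi == pytest.approx(0.9942641471812936, abs=1e-9)

    def test_matches_pingouin_icc_c1(self):
        """Independent cross-check against pingouin's ICC(C,1)."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2
        icc, lo, hi = icc_3_1(MeasurementTable(x))
        df = pd.DataFrame({
            "s": np.repeat(np.arange(8), 3),
            "m": np.tile(np.arange(3), 8),
            "y": x.ravel()})
        res = pg.intraclass_corr(df, targets="s", raters="m", ratings="y")
        row = res[res.Type == "ICC(C,1)"].iloc[0]
        assert icc == pytest.approx(row.ICC, abs=1e-9)
        # pingouin rounds the CI bounds to two decimals
        assert lo == pytest.approx(row.CI95[0], abs=0.006)
        assert hi == pytest.approx(row.CI95[1], abs=0.006)

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            icc, lo, hi = icc_3_1(MeasurementTable(x))
            assert icc == pytest.approx(oracle_icc31(x), abs=1e-10)
            assert lo <= icc <= hi and hi <= 1.0

    @given(c=st.floats(-10, 10), a=st.floats(0.1, 20))
    @settings(max_examples=40, deadline=None)
    def test_offset_and_scale_invariance(self, c, a):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(7, 2)) + rng.normal(size=(7, 1))
        ref, _, _ = icc_3_1(MeasurementTable(x))
        shifted = x + np.array([[0.0, c]])
        scaled = a * x
        assert icc_3_1(MeasurementTable(shifted))[0] == pytest.approx(
            ref, abs=1e-9)
        assert icc_3_1(MeasurementTable(scaled))[0] == pytest.approx(
            ref, abs=1e-9)

    def test_degenerate_no_subject_variance(self):
        with pytest.raises(DegenerateTableError):
            icc_3_1(table([(1, 1), (1, 1), (1, 1)]))


class TestCV:
    def test_identical_columns_zero(self):
        assert cv_percent(table([(2, 2), (5, 5)])) == 0.0

    def test_single_subject_hand_value(self):
        # SD(9,11) = √2, mean 10 → 14.142%
        t = MeasurementTable(np.array([[9.0, 11.0], [10.0, 10.0]]))
        cv_first = 100.0 * np.sqrt(2.0) / 10.0
        assert cv_percent(t) == pytest.approx(cv_first / 2.0)
        assert cv_first == pytest.approx(14.142, abs=5e-4)

    def test_scale_invariance(self):
        x = [(9, 11), (4, 5), (7, 6)]
        assert cv_percent(table(x)) == pytest.approx(
            cv_percent(MeasurementTable(10 * np.asarray(x, float))))

    def test_zero_mean_subject_undefined(self):
        with pytest.raises(DegenerateTableError):
            cv_percent(table([(1, -1), (2, 3)]))


class TestSEM:
    def test_perfect_reliability_zero(self):
        assert sem_abs(table([(1, 2), (3, 4)]), icc=1.0) == 0.0

    def test_hand_value(self):
        t = MeasurementTable(np.array([(1.0, 2.0), (3.0, 4.0)]))
        sd = t.values.std(ddof=1)
        assert sem_abs(t, icc=0.84) == pytest.approx(sd * 0.4)

    def test_zero_reliability_equals_sd(self):
        t = table([(1, 2), (3, 4), (6, 5)])
        assert sem_abs(t, 0.0) == pytest.approx(t.values.std(ddof=1))


class TestMeanDifference:
    def test_identical_zero(self):
        assert mean_difference(table([(1, 1), (2, 2)])) == 0.0

    def test_unit_offset(self):
        assert mean_difference(table([(0, 1), (0, 1)])) == 1.0

    def test_orientation_antisymmetry(self):
        x = np.array([(0.3, 0.5), (0.2, 0.1)])
        assert mean_difference(MeasurementTable(x)) == pytest.approx(
            -mean_difference(MeasurementTable(x[:, ::-1])))

    def test_requires_two_methods(self):
        with pytest.raises(ValueError):
            mean_difference(table([(1, 2, 3), (4, 5, 6)]))


class TestPearson:
    def test_affine_perfect(self):
        x = np.arange(10.0)
        res = pearson_graded(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.magnitude == "very high"

    def test_anti_monotone_affine(self):
        x = np.arange(8.0)
        res = pearson_graded(x, -3 * x + 2)
        assert res.r == pytest.approx(-1.0)
        assert res.magnitude == "very high"

    @pytest.mark.parametrize("r,label", [
        (0.1, "negligible"), (0.30, "low"), (0.45, "low"),
        (0.50, "moderate"), (0.70, "high"), (0.85, "high"),
        (0.90, "very high"), (-0.95, "very high"),
    ])
    def test_hinkle_bands_boundaries_upper(self, r, label):
        assert hinkle_magnitude(r) == label

    def test_cosine_of_centred_vectors_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            xc, yc = x - x.mean(), y - y.mean()
            cos = xc @ yc / np.sqrt((xc @ xc) * (yc @ yc))
            assert pearson_graded(x, y).r == pytest.approx(cos, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_graded(np.ones(5), np.arange(5.0))


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0
        assert res.loa_low == 0.0 == res.loa_high

    def test_hand_computed_limits(self):
        # d = (−1, 0, 1): bias 0, SD 1, LoA ±1.96
        res = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)

    @given(c=st.floats(-3, 3))
    @settings(max_examples=30, deadline=None)
    def test_translation_equivariance(self, c):
        rng = np.random.default_rng(23)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        a = bland_altman(x, y)
        b = bland_altman(x + c, y)
        assert b.bias == pytest.approx(a.bias + c, abs=1e-9)
        assert b.sd_diff == pytest.approx(a.sd_diff, abs=1e-9)
        assert b.loa_low == pytest.approx(a.loa_low + c, abs=1e-9)

    def test_summary_inversion_hand_values(self):
        # printed limits (−0.126, +0.092) → bias −0.017, SD 0.218/3.92
        bias, sd = ba_from_summary(-0.126, 0.092)
        assert bias == pytest.approx(-0.017, abs=1e-12)
        assert sd == pytest.approx(0.05561, abs=5e-6)

    def test_symmetric_limits_zero_bias(self):
        bias, _ = ba_from_summary(-0.37, 0.37)
        assert bias == 0.0

    @given(bias=st.floats(-2, 2), sd=st.floats(0.01, 3))
    @settings(max_examples=50, deadline=None)
    def test_inversion_roundtrip_identity(self, bias, sd):
        from cmjkin.agreement import BlandAltmanResult
        res = BlandAltmanResult(bias=bias, sd_diff=sd)
        b2, s2 = ba_from_summary(res.loa_low, res.loa_high)
        assert b2 == pytest.approx(bias, abs=1e-9)
        assert s2 == pytest.approx(sd, abs=1e-9)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            ba_from_summary(0.5, 0.5)


class TestSampleSize:
    def test_one_tailed_reference(self):
        # ρ=0.8, α=0.05 one-tailed, power 0.8 → Fisher-z 8.12 → 9
        assert sample_size_correlation(
            PowerQuery(rho=0.8, alpha=0.05, power=0.8, tails="one")) == 9

    def test_two_tailed_reference(self):
        # same inputs two-tailed → Fisher-z 9.50 → 10
        assert sample_size_correlation(
            PowerQuery(rho=0.8, alpha=0.05, power=0.8, tails="two")) == 10

    def test_monotone_in_rho(self):
        ns = [sample_size_correlation(PowerQuery(rho=r))
              for r in (0.3, 0.5, 0.7, 0.9)]
        assert ns == sorted(ns, reverse=True)

    def test_monotone_in_power(self):
        n_low = sample_size_correlation(PowerQuery(power=0.6))
        n_high = sample_size_correlation(PowerQuery(power=0.95))
        assert n_high >= n_low


def test_build_tables_shapes_and_orientation():
    """Report rows cover marker × variable; MD/bias oriented B − A."""
    rows = []
    rng = np.random.default_rng(31)
    for pid in range(6):
        base = {"dt_ecc": 0.45, "dt_PP": 0.31, "dt_take_off": 0.76,
                "h_Z_min": -0.3, "h_Z_max": 0.45}
        for label in ("video:A", "video:B"):
            shift = 0.01 if label == "video:B" else 0.0
            rows.append({"participant": f"P{pid}", "trial": 1,
                         "source": "video", "rater": label[-1],
                         "marker": "hip",
                         **{k: v + shift + rng.normal(0, 0.005)
                            for k, v in base.items()}})
    df = pd.DataFrame(rows)
    tab = build_tables(df, "video:A", "video:B", with_pearson=True)
    assert set(tab.variable) == {"dt_ecc", "dt_PP", "dt_take_off",
                                 "h_Z_min", "h_Z_max"}
    assert {"icc", "ci_low", "ci_high", "cv_pct", "sem", "md",
            "ba_bias", "r", "p", "magnitude"} <= set(tab.columns)
    # systematic +0.01 on B shows up with that sign
    assert tab.md.mean() == pytest.approx(0.01, abs=0.01)
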