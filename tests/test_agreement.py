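"""Bland-Altman, ICC, RMSE, ICC bands and the heteroscedasticity check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shoulderval.agreement import (
    PairedMeasurements,
    bland_altman,
    build_report,
    classify_icc,
    heteroscedasticity_check,
    icc_two_way_mixed,
    rmse,
)


def make_pairs(ref, test, outcome="ROM", movement="ABD", units="deg"):
    ref = np.asarray(ref, dtype=float)
    return PairedMeasurements(
        outcome_label=outcome,
        movement_label=movement,
        subjects=[f"S{i:02d}" for i in range(len(ref))],
        reference=ref,
        test=np.asarray(test, dtype=float),
        units=units,
    )


def icc_anova_oracle(ref, test, form="consistency"):
    """Independent brute-force oracle: two-way ANOVA mean squares obtained
    from least-squares projections onto dummy-coded design matrices."""
    Y = np.column_stack([ref, test])
    n, k = Y.shape
    y = Y.ravel()
    subj = np.repeat(np.eye(n), k, axis=0)
    meth = np.tile(np.eye(k), (n, 1))
    one = np.ones((n * k, 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    sst = rss(one)
    ssr = sst - rss(np.hstack([one, subj]))
    ssc = sst - rss(np.hstack([one, meth]))
    sse = rss(np.hstack([one, subj, meth]))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestBlandAltman:
    def test_constant_difference(self):
        p = make_pairs([10, 20, 30], [3, 13, 23])
        bias, hi, lo = bland_altman(p)
        assert bias == pytest.approx(7.0)
        assert hi == pytest.approx(7.0)
        assert lo == pytest.approx(7.0)

    def test_er_row_bias_from_means(self, rng):
        """A cohort whose per-system means are 65.3 and 39.4 must yield a
        bias of exactly 25.9 — the mean difference identity."""
        ref = rng.normal(65.3, 12.8, 24)
        ref += 65.3 - ref.mean()
        test = rng.normal(39.4, 10.4, 24)
        test += 39.4 - test.mean()
        bias, _, _ = bland_altman(make_pairs(ref, test))
        assert bias == pytest.approx(25.9, abs=1e-9)

    def test_loa_symmetry(self, rng):
        p = make_pairs(rng.normal(50, 10, 30), rng.normal(45, 10, 30))
        bias, hi, lo = bland_altman(p)
        assert hi - bias == pytest.approx(bias - lo, abs=1e-10)
        assert hi >= bias >= lo

    def test_normal_coverage(self, rng):
        d = rng.normal(5, 10, 10_000)
        p = make_pairs(d, np.zeros_like(d))
        bias, hi, lo = bland_altman(p)
        frac = np.mean((d > lo) & (d < hi))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            make_pairs([1.0], [2.0])


class TestICC:
    def test_perfect_agreement(self):
        v = np.array([10.0, 20.0, 30.0, 40.0])
        assert icc_two_way_mixed(make_pairs(v, v)) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        p = make_pairs(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
        assert abs(icc_two_way_mixed(p)) < 0.1

    def test_matches_anova_oracle_100_instances(self, rng):
        """Criterion: ICC equals the brute-force mean-squares oracle to
        1e-10 on random small cohorts."""
        for _ in range(100):
            n = rng.integers(3, 11)
            ref = rng.normal(50, 15, n)
            test = 0.8 * ref + rng.normal(0, 5, n)
            p = make_pairs(ref, test)
            for form in ("consistency", "absolute"):
                assert icc_two_way_mixed(p, form) == pytest.approx(
                    icc_anova_oracle(ref, test, form), abs=1e-10
                )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        ref = rng.normal(60, 12, 24)
        test = 0.7 * ref + rng.normal(0, 6, 24)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(24), 2),
            "rater": np.tile(["ref", "test"], 24),
            "value": np.column_stack([ref, test]).ravel(),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="value")
        res["Type"] = res["Type"].replace(
            {"ICC(C,1)": "ICC3", "ICC(A,1)": "ICC2"}
        )
        icc3 = float(res.loc[res.Type == "ICC3", "ICC"].iloc[0])
        icc2 = float(res.loc[res.Type == "ICC2", "ICC"].iloc[0])
        p = make_pairs(ref, test)
        assert icc_two_way_mixed(p, "consistency") == pytest.approx(icc3, abs=1e-9)
        assert icc_two_way_mixed(p, "absolute") == pytest.approx(icc2, abs=1e-9)

    def test_consistency_invariant_to_column_shift_absolute_not(self, rng):
        ref = rng.normal(50, 10, 20)
        test = ref + rng.normal(0, 3, 20)
        p0 = make_pairs(ref, test)
        p1 = make_pairs(ref, test + 25.0)
        assert icc_two_way_mixed(p1, "consistency") == pytest.approx(
            icc_two_way_mixed(p0, "consistency"), abs=1e-10
        )
        assert icc_two_way_mixed(p1, "absolute") < icc_two_way_mixed(p0, "absolute")

    def test_zero_variance_rejected(self):
        v = np.full(5, 7.0)
        with pytest.raises(ValueError):
            icc_two_way_mixed(make_pairs(v, v))

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            icc_two_way_mixed(make_pairs([1.0, 2.0], [1.0, 2.0]))


class TestRmse:
    def test_identical_pairs_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert rmse(make_pairs(v, v)) == 0.0

    def test_constant_difference(self):
        v = np.array([1.0, 2.0, 3.0])
        assert rmse(make_pairs(v + 3.0, v)) == pytest.approx(3.0)

    def test_elementwise_oracle(self, rng):
        ref = rng.normal(0, 10, 50)
        test = rng.normal(0, 10, 50)
        direct = np.sqrt(np.sum((ref - test) ** 2) / 50)
        assert rmse(make_pairs(ref, test)) == pytest.approx(direct, abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(
        st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)), min_size=2, max_size=40))
    def test_rmse_geq_bias_identity(self, pairs):
        ref = np.array([a for a, _ in pairs])
        test = np.array([b for _, b in pairs])
        p = make_pairs(ref, test)
        bias, _, _ = bland_altman(p)
        r = rmse(p)
        d = p.differences
        n = len(d)
        assert r >= abs(bias) - 1e-9
        assert r**2 == pytest.approx(
            bias**2 + (n - 1) / n * d.var(ddof=1), rel=1e-9, abs=1e-9
        )


class TestClassifyIcc:
    @pytest.mark.parametrize("icc,band", [
        (0.048, "poor"),
        (0.499, "poor"),
        (0.5, "moderate"),
        (0.69, "moderate"),
        (0.7, "good"),
        (0.727, "good"),   # banded by the stated edges, not prose
        (0.865, "good"),
        (0.9, "excellent"),
        (0.99, "excellent"),
        (-0.3, "poor"),
    ])
    def test_bands(self, icc, band):
        assert classify_icc(icc) == band

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(float("nan"))


class TestHeteroscedasticity:
    def test_null_rejection_rate(self, rng):
        """Constant-variance differences: tau small, p usually > 0.05."""
        rejections = 0
        reps = 300
        for _ in range(reps):
            means = rng.uniform(20, 100, 100)
            d = rng.normal(0, 5, 100)
            res = heteroscedasticity_check(make_pairs(means + d / 2, means - d / 2))
            if res.p_value < 0.05:
                rejections += 1
        assert rejections / reps < 0.1

    def test_power_when_sd_proportional_to_mean(self, rng):
        detected = 0
        reps = 300
        for _ in range(reps):
            means = rng.uniform(10, 100, 100)
            d = rng.normal(0, 0.15 * means)
            res = heteroscedasticity_check(make_pairs(means + d / 2, means - d / 2))
            if res.statistic > 0 and res.p_value < 0.05:
                detected += 1
        assert detected / reps > 0.8

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            heteroscedasticity_check(make_pairs([1, 2, 3], [1, 2, 3.5]))

    def test_plot_pairs_returned(self, rng):
        p = make_pairs(rng.normal(50, 5, 20), rng.normal(45, 5, 20))
        res = heteroscedasticity_check(p)
        np.testing.assert_allclose(res.means, p.means)
        np.testing.assert_allclose(res.differences, p.differences)


class TestBuildReport:
    def _summaries(self, rng, bias=0.0):
        rows = []
        for i in range(8):
            ref = rng.normal(100, 10)
            for system, value in (("reference", ref), ("wearable", ref - bias)):
                rows.append({
                    "subject": f"S{i:02d}", "movement": "ABD",
                    "system": system, "outcome": "ROM", "units": "deg",
                    "value": value,
                })
        return pd.DataFrame(rows)

    def test_zero_error_row(self, rng):
        rep = build_report(self._summaries(rng, bias=0.0))
        row = rep.iloc[0]
        assert row.bias == pytest.approx(0.0, abs=1e-12)
        assert row.rmse == pytest.approx(0.0, abs=1e-12)
        assert row.icc == pytest.approx(1.0)
        assert row.icc_band == "excellent"

    def test_injected_bias_recovered(self, rng):
        rep = build_report(self._summaries(rng, bias=12.5))
        assert rep.iloc[0].bias == pytest.approx(12.5, abs=1e-9)

    def test_column_schema(self, rng):
        from shoulderval.agreement import REPORT_COLUMNS

        rep = build_report(self._summaries(rng))
        assert list(rep.columns) == REPORT_COLUMNS

    def test_unpaired_subjects_dropped(self, rng):
        df = self._summaries(rng)
        df = df.drop(df[(df.subject == "S00") & (df.system == "wearable")].index)
        rep = build_report(df)
        assert rep.iloc[0].n == 7
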