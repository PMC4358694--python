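import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import allompower as ap
from allompower.exceptions import (
    ConfigurationError,
    DegenerateDataError,
    SampleSizeError,
)


def brute_force_ols(u, v):
    """Independent oracle: closed-form sums evaluated with plain loops."""
    n = len(u)
    um = sum(u) / n
    vm = sum(v) / n
    sxx = sum((x - um) ** 2 for x in u)
    syy = sum((y - vm) ** 2 for y in v)
    sxy = sum((x - um) * (y - vm) for x, y in zip(u, v))
    slope = sxy / sxx
    intercept = vm - slope * um
    r2 = sxy**2 / (sxx * syy)
    se = math.sqrt(((syy - slope * sxy) / sxx) / (n - 2))
    tq = stats.t.ppf(0.975, n - 2)
    p = 2 * stats.t.sf(abs((slope - 1) / se), n - 2)
    return slope, intercept, r2, slope - tq * se, slope + tq * se, p


def brute_force_sma(u, v):
    n = len(u)
    um = sum(u) / n
    vm = sum(v) / n
    sxx = sum((x - um) ** 2 for x in u)
    syy = sum((y - vm) ** 2 for y in v)
    sxy = sum((x - um) * (y - vm) for x, y in zip(u, v))
    r = sxy / math.sqrt(sxx * syy)
    slope = math.copysign(math.sqrt(syy / sxx), r)
    intercept = vm - slope * um
    B = stats.f.ppf(0.95, 1, n - 2) * (1 - r**2) / (n - 2)
    lo = slope * (math.sqrt(B + 1) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1) + math.sqrt(B))
    if slope < 0:
        lo, hi = hi, lo
    d = [y - x for x, y in zip(u, v)]
    s = [y + x for x, y in zip(u, v)]
    rp = np.corrcoef(d, s)[0, 1]
    p = 2 * stats.t.sf(abs(rp) * math.sqrt((n - 2) / (1 - rp**2)), n - 2)
    return slope, intercept, r**2, lo, hi, p


def random_pairs(rng, n):
    u = rng.normal(2.0, 0.5, n)
    v = 0.3 + rng.uniform(0.5, 1.5) * u + rng.normal(0, 0.1, n)
    return u, v


class TestClosedForms:
    def test_exact_line(self):
        res = ap.fit_ols([0, 1, 2], [0, 1, 2])
        assert (res.slope, res.intercept, res.r2) == (1.0, 0.0, 1.0)

    def test_ols_hand_example(self):
        res = ap.fit_ols([0, 1, 2], [0.1, 0.9, 2.0])
        assert res.slope == pytest.approx(0.95)
        assert res.intercept == pytest.approx(0.05)
        assert round(res.r2, 4) == 0.9918

    def test_sma_hand_example(self):
        res = ap.fit_sma([0, 1, 2], [0.1, 0.9, 2.0])
        assert round(res.slope, 4) == 0.9539
        # CI via B with F(0.95; 1, 1) = 161.45
        assert res.ci_low == pytest.approx(0.356, abs=2e-3)
        assert res.ci_high == pytest.approx(2.556, abs=2e-3)

    def test_sma_exact_line_degenerate_ci(self):
        res = ap.fit_sma([0, 1, 2, 3], [0, 2, 4, 6])
        assert res.slope == pytest.approx(2.0)
        assert res.ci_low == pytest.approx(2.0)
        assert res.ci_high == pytest.approx(2.0)
        assert res.p_vs_1 == 0.0

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(101)
        for _ in range(20):
            u, v = random_pairs(rng, n)
            o = ap.fit_ols(u, v)
            e = brute_force_ols(list(u), list(v))
            for got, want in zip(
                (o.slope, o.intercept, o.r2, o.ci_low, o.ci_high, o.p_vs_1), e
            ):
                assert got == pytest.approx(want, abs=1e-10)
            s = ap.fit_sma(u, v)
            e = brute_force_sma(list(u), list(v))
            for got, want in zip(
                (s.slope, s.intercept, s.r2, s.ci_low, s.ci_high, s.p_vs_1), e
            ):
                assert got == pytest.approx(want, abs=1e-10)


class TestFitProperties:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.1, 5.0, allow_nan=False),
                st.floats(-3.0, 3.0, allow_nan=False),
            ),
            min_size=3,
            max_size=25,
            unique_by=lambda p: p[0],
        )
    )
    def test_sma_ols_identity_holds_for_arbitrary_pairs(self, pairs):
        """|SMA slope| = |OLS slope| / |r| on any non-degenerate dataset."""
        u = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        try:
            s = ap.fit_sma(u, v)
            o = ap.fit_ols(u, v)
        except DegenerateDataError:
            return
        r = math.sqrt(o.r2)
        assert abs(s.slope) == pytest.approx(abs(o.slope) / r, rel=1e-9)
        assert s.ci_low <= s.slope <= s.ci_high

    def test_sma_equals_ols_over_r(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            u, v = random_pairs(rng, int(rng.integers(3, 40)))
            o = ap.fit_ols(u, v)
            s = ap.fit_sma(u, v)
            r = math.sqrt(o.r2)
            assert abs(s.slope) == pytest.approx(abs(o.slope) / r, abs=1e-10)
            assert abs(s.slope) >= abs(o.slope) - 1e-12

    def test_ci_and_test_agree_on_isometry(self):
        # p < 0.05 iff the 95% CI excludes 1, for both methods
        rng = np.random.default_rng(23)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            u = rng.normal(0, 1, n)
            v = rng.normal(0, 0.2, n) + u * rng.uniform(0.7, 1.3)
            o = ap.fit_ols(u, v)
            assert (o.p_vs_1 < 0.05) == not_in_ci(o)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            ap.fit_ols([1, 1, 1], [0, 1, 2])
        with pytest.raises(DegenerateDataError):
            ap.fit_sma([0, 1, 2], [5, 5, 5])
        with pytest.raises(SampleSizeError):
            ap.fit_ols([0, 1], [0, 1])
        with pytest.raises(ConfigurationError):
            ap.fit_pair([0, 1, 2], [0, 1, 2], "pca")


def not_in_ci(res):
    return not (res.ci_low <= 1.0 <= res.ci_high)


class TestClassification:
    def _res(self, lo, hi, p):
        return ap.RegressionResult("ols", 10, (lo + hi) / 2, 0.0, 0.9, lo, hi, p)

    def test_categories_from_ci(self):
        assert ap.classify(self._res(1.117, 1.147, 1e-6)).category == "positive"
        assert ap.classify(self._res(0.643, 0.689, 1e-6)).category == "negative"
        assert ap.classify(self._res(0.95, 1.05, 0.5)).category == "isometric"

    def test_ci_endpoint_exactly_one_is_isometric(self):
        assert ap.classify(self._res(1.0, 1.2, 0.04)).category == "isometric"
        assert ap.classify(self._res(0.8, 1.0, 0.04)).category == "isometric"

    def test_hard_vs_soft_isometry_threshold(self):
        assert ap.classify(self._res(0.99, 1.03, 0.0898)).iso_subtype == "soft"
        assert ap.classify(self._res(0.99, 1.03, 0.1199)).iso_subtype == "soft"
        assert ap.classify(self._res(0.97, 1.02, 0.2266)).iso_subtype == "hard"
        assert ap.classify(self._res(0.97, 1.02, 0.7146)).iso_subtype == "hard"
        # threshold is a knob
        assert ap.classify(self._res(0.99, 1.03, 0.1199),
                           soft_iso_p=0.10).iso_subtype == "hard"

    def test_allometric_has_no_iso_subtype(self):
        assert ap.classify(self._res(1.1, 1.2, 1e-6)).iso_subtype == "not-applicable"

    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, ""), (0.1199, ""), (0.04, "*"), (0.009, "**"),
         (0.0009, "***"), (0.00009, "****")],
    )
    def test_significance_stars(self, p, stars):
        assert ap.significance_stars(p) == stars


class TestRegressAll:
    def test_alligator_table_has_22_entries(self, alligator_table):
        fits = ap.regress_all(alligator_table, "ols")
        assert len(fits) == 22
        assert all(f.result is not None for f in fits)

    @pytest.mark.parametrize("method", ["ols", "sma"])
    def test_noise_free_categories(self, tiny_table, method):
        cats = {
            f.variable_id: f.category.category
            for f in ap.regress_all(tiny_table, method)
        }
        assert cats == {"half": "negative", "iso": "isometric", "double": "positive"}

    def test_constant_column_flagged_not_fatal(self, tiny_table):
        frame = tiny_table.data.assign(flat=5.0)
        fits = ap.regress_all(ap.MeasurementTable(frame, "ref"), "sma")
        by_id = {f.variable_id: f for f in fits}
        assert by_id["flat"].error is not None
        assert by_id["double"].result is not None


class TestAllometryModel:
    def test_results_object_round_trip(self, alligator_table, tmp_path):
        res = ap.AllometryModel(alligator_table, "sma").fit()
        summary = res.summary()
        assert len(summary) == 22
        assert set(res.true_categories().values()) <= set(
            ("positive", "negative", "isometric")
        )
        out = tmp_path / "summary.csv"
        res.to_csv(out)
        assert out.exists()

    def test_from_dataframe_constructor(self, tiny_table):
        res = ap.AllometryModel.from_dataframe(
            tiny_table.data, "ref", method="ols"
        ).fit()
        assert res.results["double"].slope == pytest.approx(2.0, abs=1e-9)

    def test_sma_slope_steeper_than_ols_on_noisy_data(self, alligator_table):
        ols = ap.AllometryModel(alligator_table, "ols").fit()
        sma = ap.AllometryModel(alligator_table, "sma").fit()
        for var in ols.results:
            assert abs(sma.results[var].slope) >= abs(ols.results[var].slope) - 1e-12


class TestCoverage:
    @pytest.mark.parametrize("method", ["ols", "sma"])
    def test_ci_covers_method_estimand(self, method):
        """Nominal 95% coverage of the slope CI on the generating model.

        Each method's CI is checked against its own population estimand:
        the generating slope b for OLS, and the population SMA slope
        b sqrt(1 + sigma^2/(b^2 Var u)) for SMA, which exceeds b slightly
        because the noise enters the dependent variable only.
        """
        b, sigma = 1.1, 0.05
        var_u = (math.log10(689) - math.log10(29)) ** 2 / 12
        target = {
            "ols": b,
            "sma": math.sqrt(b * b * var_u + sigma * sigma) / math.sqrt(var_u),
        }[method]
        spec = ap.AllometryModelSpec(
            (29.0, 689.0), (ap.VariableSpec("v", 0.0, b, sigma),)
        )
        covered = 0
        reps = 1000
        for seed in range(reps):
            table = ap.simulate_dataset(spec, 50, seed=seed)
            u, v = ap.log_transform(table).pair("v")
            res = ap.fit_pair(u, v, method)
            covered += res.ci_low <= target <= res.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.02)
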