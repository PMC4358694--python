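import numpy as np
import pandas as pd
import pytest

import allompower as ap
from allompower.exceptions import ConfigurationError, ValidationError
from allompower.power import CATEGORIES


def make_curve(props_by_n, reps=100, truth_col="positive"):
    """PowerCurve with the given proportion of `truth_col` per n (rest isometric)."""
    rows = []
    for n, p in props_by_n.items():
        k = int(round(p * reps))
        counts = dict.fromkeys(CATEGORIES, 0)
        counts[truth_col] = k
        counts["isometric"] += reps - k
        rows.append({"n": n, **counts, "failed": 0, "reps": reps})
    frame = pd.DataFrame(rows).set_index("n")
    return ap.PowerCurve("v", "ols", "random", frame)


@pytest.fixture(scope="module")
def steep_table():
    """Noise-free strongly allometric variable (slope 2)."""
    spec = ap.AllometryModelSpec(
        (29.0, 689.0), (ap.VariableSpec("v", 0.0, 2.0, 0.0),)
    )
    return ap.simulate_dataset(spec, 60, seed=6)


class TestRunSweep:
    def test_noise_free_full_power_everywhere(self, steep_table):
        curve = ap.run_sweep(steep_table, "v", "ols", "random",
                             range(3, 11), reps=50, seed=1)
        assert (curve.proportion("positive") == 1.0).all()
        assert (curve.counts["failed"] == 0).all()

    def test_deterministic_given_seed(self, alligator_table):
        kwargs = dict(method="ols", scheme="random", n_range=range(3, 8),
                      reps=25, seed=9)
        a = ap.run_sweep(alligator_table, "7", **kwargs)
        b = ap.run_sweep(alligator_table, "7", **kwargs)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_matches_naive_reference_loop(self, alligator_table):
        # engine equivalence: an unvectorised re-run over the same substreams
        n, reps, seed = 12, 50, 4
        curve = ap.run_sweep(alligator_table, "7", "sma", "even_occupancy",
                             [n], reps=reps, seed=seed)
        logt = ap.log_transform(alligator_table)
        U = logt.data["6"].to_numpy()
        V = logt.data["7"].to_numpy()
        ref = alligator_table.reference_values()
        tally = dict.fromkeys(CATEGORIES, 0)
        for rep in range(reps):
            rng = ap.substream(seed, "even_occupancy", "7", n, rep)
            idx = ap.draw("even_occupancy", ref, n, rng)
            res = ap.fit_pair(U[idx], V[idx], "sma")
            tally[ap.classify(res).category] += 1
        for cat in CATEGORIES:
            assert curve.counts.loc[n, cat] == tally[cat]

    def test_proportions_sum_to_one(self, alligator_table):
        curve = ap.run_sweep(alligator_table, "10", "ols", "random",
                             range(3, 9), reps=40, seed=2)
        p = curve.proportions()
        total = p["p_positive"] + p["p_negative"] + p["p_isometric"]
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_infeasible_sizes_skipped_not_fatal(self, steep_table):
        # even-length bins empty out quickly on a log-uniform series
        curve = ap.run_sweep(steep_table, "v", "ols", "even_length",
                             range(3, 31), reps=5, seed=3)
        assert curve.skipped
        assert set(curve.counts.index).isdisjoint(curve.skipped)

    def test_unknown_scheme_rejected(self, steep_table):
        with pytest.raises(ConfigurationError):
            ap.run_sweep(steep_table, "v", "ols", "bootstrap", [5], reps=2, seed=0)


class TestMinSampleForAgreement:
    def test_first_crossing_worked_example(self):
        curve = make_curve({23: 0.93, 24: 0.96, 25: 0.97})
        res = ap.min_sample_for_agreement(curve, "positive")
        assert res.min_n == 24 and not res.censored

    def test_all_above_level_gives_sweep_start(self):
        curve = make_curve({n: 1.0 for n in range(3, 10)})
        assert ap.min_sample_for_agreement(curve, "positive").min_n == 3

    def test_censored_when_level_never_reached(self):
        curve = make_curve({n: 0.5 for n in range(3, 101)})
        res = ap.min_sample_for_agreement(curve, "positive")
        assert res.censored and res.min_n is None and res.sweep_max == 100
        assert str(res) == ">100"

    def test_isometric_truth_not_applicable(self):
        curve = make_curve({3: 1.0})
        res = ap.min_sample_for_agreement(curve, "isometric")
        assert not res.applicable and str(res) == "n/a"

    def test_first_crossing_invariant_to_larger_sweep_sizes(self):
        base = {23: 0.93, 24: 0.96, 25: 0.40}
        short = ap.min_sample_for_agreement(make_curve(base), "positive")
        extended = {**base, **{n: 0.99 for n in range(26, 60)}}
        long = ap.min_sample_for_agreement(make_curve(extended), "positive")
        assert short.min_n == long.min_n == 24

    def test_persistent_variant_requires_stability(self):
        curve = make_curve({23: 0.96, 24: 0.40, 25: 0.99, 26: 0.99})
        res = ap.min_sample_for_agreement(curve, "positive", persistent=True)
        assert res.min_n == 25

    def test_empty_curve_rejected(self):
        empty = ap.PowerCurve(
            "v", "ols", "random",
            pd.DataFrame(columns=[*CATEGORIES, "failed", "reps"]),
        )
        with pytest.raises(ValidationError):
            ap.min_sample_for_agreement(empty, "positive")


class TestErrorRates:
    def _curve(self, pos, iso, neg, n=10, reps=100):
        frame = pd.DataFrame(
            [{"n": n, "positive": pos, "isometric": iso, "negative": neg,
              "failed": reps - pos - iso - neg, "reps": reps}]
        ).set_index("n")
        return ap.PowerCurve("v", "ols", "random", frame)

    def test_allometric_truth_definitions(self):
        rates = ap.error_rates(self._curve(90, 8, 2), "positive").rates
        assert rates.loc[10, "false_isometry"] == pytest.approx(0.08)
        assert rates.loc[10, "sign_error"] == pytest.approx(0.02)
        assert rates.loc[10, "false_allometry"] == 0.0

    def test_isometric_truth_definitions(self):
        rates = ap.error_rates(self._curve(3, 95, 2), "isometric").rates
        assert rates.loc[10, "false_allometry"] == pytest.approx(0.05)
        assert rates.loc[10, "false_isometry"] == 0.0
        assert rates.loc[10, "sign_error"] == 0.0

    def test_perfect_power_means_zero_error(self):
        rates = ap.error_rates(self._curve(100, 0, 0), "positive").rates
        assert (rates.loc[10] == 0.0).all()

    def test_aggregate_mean_and_sd(self):
        a = ap.error_rates(self._curve(80, 20, 0), "positive")
        b = ap.error_rates(self._curve(60, 40, 0), "positive")
        agg = ap.aggregate_error_rates([a, b]).rates
        assert agg.loc[10, "false_isometry"] == pytest.approx(0.3)
        assert agg.loc[10, "false_isometry_sd"] == pytest.approx(0.1414, abs=1e-4)
        same = ap.aggregate_error_rates([a, a]).rates
        assert same.loc[10, "false_isometry_sd"] == 0.0

    def test_mismatched_grids_rejected(self):
        a = ap.error_rates(self._curve(80, 20, 0, n=10), "positive")
        b = ap.error_rates(self._curve(80, 20, 0, n=11), "positive")
        with pytest.raises(ValidationError):
            ap.aggregate_error_rates([a, b])


@pytest.fixture(scope="module")
def analysis_results():
    spec = ap.AllometryModelSpec(
        (29.0, 689.0),
        (
            ap.VariableSpec("steep", 0.0, 1.4, 0.05),
            ap.VariableSpec("shallow", 0.0, 0.6, 0.05),
            ap.VariableSpec("flat", 0.0, 1.0, 0.05),
        ),
    )
    table = ap.simulate_dataset(spec, 108, seed=31)
    return ap.SubsamplingPowerAnalysis(
        table, method="ols", scheme="random", n_range=range(3, 21),
        reps=60, seed=5,
    ).run()


class TestSubsamplingPowerAnalysis:
    def test_tables_are_complete(self, analysis_results):
        assert set(analysis_results.curves) == {"steep", "shallow", "flat"}
        power = analysis_results.power_table()
        assert set(power["variable"]) == {"steep", "shallow", "flat"}
        ms = analysis_results.min_sample_table()
        assert len(ms) == 3
        err = analysis_results.error_rate_table()
        assert "aggregate" in set(err["variable"])

    def test_truth_comes_from_full_sample_fit(self, analysis_results):
        truths = analysis_results.full_fit.true_categories()
        assert truths["steep"] == "positive"
        assert truths["shallow"] == "negative"
        by_var = {m.variable_id: m for m in analysis_results.min_samples}
        assert by_var["steep"].true_category == "positive"

    def test_scaling_points_use_full_sample_slopes(self, analysis_results):
        points = {round(p.x, 1) for p in analysis_results.scaling_points()}
        # only allometric truths yield points; slopes near 1.4 and 0.6
        slopes = {round(analysis_results.full_fit.results[v].slope, 1)
                  for v, c in analysis_results.full_fit.true_categories().items()
                  if c != "isometric"}
        assert points == slopes
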