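"""Pooled summaries, median splits, Kaplan–Meier and Cox proportional
hazards, including a brute-force partial-likelihood oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from nestcamo.survival import (NestOutcome, SpeciesSummary, cox_ph,
                               kaplan_meier, logistic_interaction,
                               median_split, outcomes_to_frame,
                               pooled_group_stats)

# Published per-species flight-distance summaries (n, mean, min, max, sd)
PLOVER_COURSER_ROWS = [
    ("three-banded plover", 4, 39.0, 26, 56, 13.71),
    ("Temminck's courser", 8, 54.63, 33, 77, 12.69),
    ("bronze-winged courser", 14, 42.36, 9, 77, 17.21),
    ("three-banded courser", 3, 8.0, 4, 15, 6.08),
    ("crowned plover", 24, 84.75, 27, 180, 41.28),
    ("wattled plover", 2, 80.0, 50, 110, 42.43),
]
NIGHTJAR_ROWS = [
    ("Mozambique nightjar", 32, 1.68, 0.5, 4, 0.85),
    ("fiery-necked nightjar", 41, 2.08, 0.5, 10, 1.71),
    ("pennant-winged nightjar", 5, 1.94, 1.2, 4, 1.18),
]


def rows_to_summaries(rows):
    return [SpeciesSummary(species=s, n=n, mean=m, min=lo, max=hi, sd=sd)
            for s, n, m, lo, hi, sd in rows]


class TestPooledGroupStats:
    # The published per-species rows are rounded to 2 dp, so the pooled SD
    # carries up to one unit of last-digit rounding error.
    def test_plover_courser_totals(self):
        n, mean, sd = pooled_group_stats(rows_to_summaries(PLOVER_COURSER_ROWS))
        assert n == 55
        assert mean == pytest.approx(61.89, abs=0.005)
        assert sd == pytest.approx(37.61, abs=0.01)

    def test_nightjar_totals(self):
        n, mean, sd = pooled_group_stats(rows_to_summaries(NIGHTJAR_ROWS))
        assert n == 78
        assert mean == pytest.approx(1.91, abs=0.005)
        assert sd == pytest.approx(1.38, abs=0.01)

    def test_single_group_identity(self):
        s = SpeciesSummary("one", 10, 5.0, 1, 9, 2.5)
        n, mean, sd = pooled_group_stats([s])
        assert (n, mean, sd) == (10, 5.0, 2.5)

    def test_pooled_mean_within_range_of_means(self, rng):
        rows = [SpeciesSummary(f"s{i}", int(rng.integers(2, 30)),
                               float(rng.uniform(0, 100)), 0, 200,
                               float(rng.uniform(0, 20))) for i in range(5)]
        _, mean, _ = pooled_group_stats(rows)
        means = [r.mean for r in rows]
        assert min(means) <= mean <= max(means)

    def test_matches_raw_data_pooling(self, rng):
        """Pooling summaries equals computing stats on the concatenated
        raw samples (ddof=1 throughout)."""
        samples = [rng.normal(rng.uniform(0, 10), rng.uniform(1, 3),
                              size=rng.integers(2, 40)) for _ in range(4)]
        rows = [SpeciesSummary(f"s{i}", len(x), x.mean(), x.min(), x.max(),
                               x.std(ddof=1)) for i, x in enumerate(samples)]
        n, mean, sd = pooled_group_stats(rows)
        allx = np.concatenate(samples)
        assert mean == pytest.approx(allx.mean())
        assert sd == pytest.approx(allx.std(ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_group_stats([])


class TestMedianSplit:
    def test_even_count(self):
        np.testing.assert_array_equal(median_split([1, 2, 3, 4]),
                                      ["low", "low", "high", "high"])

    def test_all_equal_go_low(self):
        assert set(median_split([5, 5, 5])) == {"low"}

    def test_tie_with_median_goes_low(self):
        np.testing.assert_array_equal(median_split([5, 1, 9]),
                                      ["low", "low", "high"])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=40).round(2) + 0.01
        df = pd.DataFrame({"time_days": times, "event": 1})
        km = kaplan_meier(df)
        for _, row in km.iterrows():
            empirical = (times > row["time"]).mean()
            assert row["survival"] == pytest.approx(empirical, abs=1e-9)

    def test_hand_product_limit(self):
        df = pd.DataFrame({"time_days": [1, 2, 3], "event": [1, 0, 1]})
        km = kaplan_meier(df).set_index("time")
        assert km.loc[1, "survival"] == pytest.approx(2 / 3)
        # at t=3 the risk set is one subject with one event
        assert km.loc[3, "survival"] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        df = pd.DataFrame({"time_days": [2, 5, 9], "event": 0})
        km = kaplan_meier(df)
        np.testing.assert_allclose(km["survival"], 1.0)

    def test_non_increasing_and_ci_clipped(self, rng):
        df = pd.DataFrame({"time_days": rng.exponential(5, 60) + 0.1,
                           "event": rng.integers(0, 2, 60)})
        km = kaplan_meier(df)
        assert np.all(np.diff(km["survival"]) <= 1e-12)
        assert (km["ci_low"] >= 0).all() and (km["ci_high"] <= 1).all()
        assert (km["ci_low"] <= km["survival"] + 1e-12).all()
        assert (km["survival"] <= km["ci_high"] + 1e-12).all()

    def test_groups_reported_separately(self, rng):
        df = pd.DataFrame({"time_days": rng.exponential(5, 30) + 0.1,
                           "event": 1})
        km = kaplan_meier(df, groups=np.repeat(["a", "b"], 15))
        assert set(km["group"]) == {"a", "b"}


def neg_log_partial_likelihood(beta, times, events, x):
    """Direct enumeration of the Cox partial likelihood (no ties)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


class TestCoxPH:
    def standardized(self, x):
        return (x - x.mean()) / x.std()

    def test_matches_brute_force_oracle(self, rng):
        """β̂ on ≤ 8 subjects (no ties) equals the maximizer of the
        explicitly enumerated partial likelihood to 1e-6."""
        times = np.array([3.0, 1.0, 7.5, 2.2, 5.1, 9.9, 4.4, 6.6])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = self.standardized(rng.normal(size=8))
        df = pd.DataFrame({"time_days": times, "event": events, "x": x})
        fit = cox_ph(df, ["x"])
        oracle = minimize_scalar(
            neg_log_partial_likelihood, args=(times, events, x),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-12})
        assert fit["x"]["beta"] == pytest.approx(oracle.x, abs=1e-6)

    def test_score_at_zero_is_event_covariate_deviation(self, rng):
        """dℓ/dβ at β=0 equals Σ over events of (x_i − risk-set mean)."""
        times = rng.exponential(5, 12)
        times += np.arange(12) * 1e-4        # break ties
        events = rng.integers(0, 2, 12)
        events[0] = 1
        x = rng.normal(size=12)
        eps = 1e-6
        score = -(neg_log_partial_likelihood(eps, times, events, x)
                  - neg_log_partial_likelihood(-eps, times, events, x)) / (2 * eps)
        expected = sum(x[i] - x[times >= times[i]].mean()
                       for i in range(12) if events[i] == 1)
        assert score == pytest.approx(expected, abs=1e-4)

    def test_null_covariate_type_one_error(self):
        """A covariate unrelated to the hazard rarely reaches |Z| > 1.96."""
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(5000 + rep)
            n = 200
            t = rng.exponential(10, n)
            c = rng.exponential(20, n)
            df = pd.DataFrame({
                "time_days": np.minimum(t, c) + 1e-9,
                "event": (t <= c).astype(int),
                "x": rng.normal(size=n)})
            if abs(cox_ph(df, ["x"])["x"]["z"]) < 1.96:
                hits += 1
        assert hits >= 45

    def test_recovers_known_effect(self):
        """β = 1 on a standardized covariate, ~50% censoring: β̂ within
        3 SE of truth."""
        rng = np.random.default_rng(77)
        n = 200
        x = self.standardized(rng.normal(size=n))
        t = rng.exponential(1 / np.exp(1.0 * x))
        c = rng.exponential(np.median(t) * 1.5, n)
        df = pd.DataFrame({"time_days": np.minimum(t, c) + 1e-9,
                           "event": (t <= c).astype(int), "x": x})
        fit = cox_ph(df, ["x"])
        assert abs(fit["x"]["beta"] - 1.0) < 3 * fit["x"]["se"]

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_days": [1.0, 2.0], "event": [0, 0],
                           "x": [0.1, 0.9]})
        with pytest.raises(ValueError, match="event"):
            cox_ph(df, ["x"])


class TestLogisticInteraction:
    def test_labelled_as_approximation_and_fits(self, rng):
        n = 150
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        logit = 0.5 * x - 0.5 * y + 1.0 * x * y
        p = 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({"x": x, "y": y,
                           "fate": rng.binomial(1, p)})
        res = logistic_interaction(df, "fate", "x", "y")
        assert "no random effects" in res["model"]
        assert res["params"]["x:y"] > 0


def test_nest_outcome_validation():
    with pytest.raises(ValueError):
        NestOutcome("n1", "sp", -1.0, 1)
    with pytest.raises(ValueError):
        NestOutcome("n1", "sp", 5.0, 2)
    df = outcomes_to_frame([NestOutcome("n1", "sp", 5.0, 1, "depredated")])
    assert list(df.columns) == ["nest_id", "species", "time_days", "event",
                                "censor_reason"]
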