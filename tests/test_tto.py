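"""Time-to-onset computation, Weibull MLE and failure-type classification."""
import numpy as np
import pytest
from scipy import stats

from faersig.io import parse_raw_date
from faersig.tto import (
    TTOSample,
    WeibullFitError,
    classify_failure,
    collect_tto_sample,
    compute_tto,
    tto_result,
    tto_summary,
    weibull_fit,
)
from helpers import toy_dataset

PT = "CONSTIPATION"


class TestComputeTto:
    @pytest.mark.parametrize(
        "event, start, days, reason",
        [
            ("20200104", "20200101", 3.0, None),
            ("20191231", "20200101", None, "event_before_start"),
            ("20200101", "20200101", 0.5, None),  # same-day adjustment
            ("20200104", "202001", None, "partial_precision"),
            ("2020", "20200101", None, "partial_precision"),
            ("", "20200101", None, "missing_date"),
            ("20200104", "", None, "missing_date"),
            ("20201340", "20200101", None, "invalid_date"),
        ],
    )
    def test_cases(self, event, start, days, reason):
        got_days, got_reason = compute_tto(parse_raw_date(event), parse_raw_date(start))
        assert got_days == days
        assert got_reason == reason


class TestSummary:
    def test_simple_quartiles(self):
        s = TTOSample("D", np.array([1.0, 2, 3, 4, 5]))
        assert tto_summary(s) == (3.0, 2.0, 4.0)

    def test_median_three_values(self):
        # brute force: median of a sorted odd-length sample is the middle value
        s = TTOSample("D", np.array([2.0, 3.0, 9.0]))
        med, q1, q3 = tto_summary(s)
        assert med == sorted([2.0, 3.0, 9.0])[1] == 3.0

    def test_same_day_counts_as_zero_in_descriptives(self):
        s = TTOSample("D", np.array([0.5, 0.5, 0.5]))
        assert tto_summary(s) == (0.0, 0.0, 0.0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="empty"):
            tto_summary(TTOSample("D", np.array([])))


class TestWeibullFit:
    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(12345)
        x = 50.0 * rng.weibull(0.6, size=5000)
        f = weibull_fit(x)
        assert f.alpha == pytest.approx(50.0, rel=0.05)
        assert f.beta == pytest.approx(0.6, rel=0.05)
        assert f.alpha_lo <= 50.0 <= f.alpha_hi
        assert f.beta_lo <= 0.6 <= f.beta_hi

    def test_matches_scipy_mle(self):
        """Independent oracle: scipy's Weibull MLE with location fixed at 0."""
        rng = np.random.default_rng(99)
        x = 20.0 * rng.weibull(0.8, size=400)
        f = weibull_fit(x)
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        assert f.beta == pytest.approx(c, rel=1e-5)
        assert f.alpha == pytest.approx(scale, rel=1e-5)

    def test_exponential_special_case(self):
        # shape 1 truth: CI covers 1, fitted median ~ alpha * ln 2
        rng = np.random.default_rng(4)
        x = rng.exponential(40.0, size=3000)
        f = weibull_fit(x)
        assert f.beta_lo <= 1.0 <= f.beta_hi
        fitted_median = f.alpha * np.log(2.0) ** (1.0 / f.beta)
        assert fitted_median == pytest.approx(40.0 * np.log(2.0), rel=0.1)

    def test_identical_values_error(self):
        with pytest.raises(WeibullFitError, match="identical"):
            weibull_fit(np.array([1.0, 1.0, 1.0]))

    def test_too_few_values_error(self):
        with pytest.raises(WeibullFitError, match="n >= 3"):
            weibull_fit(np.array([1.0, 2.0]))

    def test_nonpositive_values_error(self):
        with pytest.raises(WeibullFitError, match="positive"):
            weibull_fit(np.array([0.0, 1.0, 2.0]))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        x = 30.0 * rng.weibull(0.7, size=300)
        f1 = weibull_fit(x)
        f2 = weibull_fit(7.25 * x)
        assert f2.alpha == pytest.approx(7.25 * f1.alpha, rel=1e-8)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-8)

    def test_ci_coverage_over_replicates(self):
        # 200 replicates at n=500: nominal-95% CI coverage must land in [90%, 99%]
        hits_a = hits_b = 0
        for i in range(200):
            rng = np.random.default_rng(50_000 + i)
            x = 50.0 * rng.weibull(0.6, size=500)
            f = weibull_fit(x)
            hits_a += f.alpha_lo <= 50.0 <= f.alpha_hi
            hits_b += f.beta_lo <= 0.6 <= f.beta_hi
        assert 0.90 <= hits_a / 200 <= 0.99
        assert 0.90 <= hits_b / 200 <= 0.99

    def test_constant_hazard_classified_random(self):
        # shape=1 truth: "random failure" classification in >= 80% of replicates
        hits = 0
        for i in range(50):
            rng = np.random.default_rng(i)
            x = rng.exponential(40.0, size=1000)
            f = weibull_fit(x)
            hits += classify_failure(f.beta, f.beta_lo, f.beta_hi) == "random"
        assert hits / 50 >= 0.8

    def test_bootstrap_ci(self):
        rng = np.random.default_rng(21)
        x = 30.0 * rng.weibull(0.6, size=60)
        f = weibull_fit(x, ci_method="bootstrap", n_boot=200, seed=5)
        assert f.alpha_lo < f.alpha < f.alpha_hi
        assert f.beta_lo < f.beta < f.beta_hi


@pytest.mark.parametrize(
    "beta, lo, hi, expected",
    [
        (0.55, 0.52, 0.59, "early"),
        (1.0, 0.9, 1.1, "random"),
        (1.4, 1.2, 1.6, "wear-out"),
        (0.5, float("nan"), 0.9, "indeterminate"),
    ],
)
def test_classify_failure(beta, lo, hi, expected):
    assert classify_failure(beta, lo, hi) == expected


class TestCollectSample:
    def test_values_and_exclusion_accounting(self):
        specs = [
            {"caseid": "A", "drugs": [("X", "PS", 1)], "pts": [PT],
             "event_dt": "20230110", "starts": {1: "20230101"}},        # 9 days
            {"caseid": "B", "drugs": [("X", "PS", 1)], "pts": [PT],
             "event_dt": "20230101", "starts": {1: "20230110"}},        # event first
            {"caseid": "C", "drugs": [("X", "PS", 1)], "pts": [PT],
             "event_dt": "202301", "starts": {1: "20230101"}},          # partial event
            {"caseid": "D", "drugs": [("X", "PS", 1)], "pts": [PT],
             "event_dt": "20230110"},                                   # no therapy row
            {"caseid": "E", "drugs": [("X", "PS", 1)], "pts": [PT],
             "event_dt": "20230110", "starts": {1: "202301"}},          # partial start
            {"caseid": "F", "drugs": [("X", "PS", 1)], "pts": ["NAUSEA"],
             "event_dt": "20230110", "starts": {1: "20230101"}},        # not the event
        ]
        sample = collect_tto_sample(toy_dataset(specs), "X", PT)
        assert list(sample.values) == [9.0]
        assert sample.n_excluded_by_reason["event_before_start"] == 1
        assert sample.n_excluded_by_reason["partial_precision"] == 2
        assert sample.n_excluded_by_reason["missing_date"] == 1
        assert sample.n_candidates == 5  # F never was a candidate

    def test_earliest_day_precision_start_used(self):
        specs = [{
            "caseid": "A", "drugs": [("X", "PS", 1), ("X", "PS", 2)], "pts": [PT],
            "event_dt": "20230110",
            "starts": {1: "20230105", 2: "20230101"},
        }]
        sample = collect_tto_sample(toy_dataset(specs), "X", PT)
        assert list(sample.values) == [9.0]

    def test_result_pipeline(self, synth):
        ds = synth["result"].dataset
        pt = synth["ledger"]["target_pt"]
        sample = collect_tto_sample(ds, "SEVELAMER", pt)
        res = tto_result(sample, seed=1)
        assert res.n == len(sample.values)
        assert res.q1 <= res.median <= res.q3
        if res.fit is not None:
            assert res.fit.alpha > 0 and res.fit.beta > 0
            assert res.fit.alpha_lo <= res.fit.alpha <= res.fit.alpha_hi
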