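"""ROR/PRR/chi2/RRR formulas, MGPS shrinkage, BCPNN IC, signal criteria."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faersig.contingency import ContingencyTable
from faersig.disproportionality import (
    MgpsFitError,
    SignalCriteria,
    bcpnn_ic,
    chi2_statistic,
    classify_signals,
    ebgm_estimate,
    mgps_fit_prior,
    prr_estimate,
    ror_estimate,
    rrr_estimate,
)

T_STD = ContingencyTable(10, 90, 100, 9900)
T_NULL = ContingencyTable(10, 90, 100, 900)  # a/b == c/d


# -- direct-formula oracles (independent re-derivations used for checking) --

def oracle_ror(a, b, c, d):
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-1.959963984540054 * se), ror * math.exp(1.959963984540054 * se)


def oracle_prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def oracle_chi2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def oracle_rrr(a, b, c, d):
    n = a + b + c + d
    return a * n / ((a + b) * (a + c))


class TestRor:
    def test_value_and_ci(self):
        # frozen from the direct-formula oracle: 11*exp(-+1.96*se), se=0.348155
        est = ror_estimate(T_STD)
        assert est.value == pytest.approx(11.0)
        assert est.lo == pytest.approx(5.5596, abs=0.001)
        assert est.hi == pytest.approx(21.7645, abs=0.001)

    def test_null_table_exactly_one(self):
        assert ror_estimate(T_NULL).value == pytest.approx(1.0, rel=1e-14)

    def test_zero_cell_undefined(self):
        est = ror_estimate(ContingencyTable(0, 90, 100, 9900))
        assert not est.defined and est.reason == "zero_cell"
        assert math.isnan(est.value)

    def test_continuity_correction_defines_zero_cell(self):
        est = ror_estimate(ContingencyTable(0, 90, 100, 9900), continuity=True)
        assert est.defined and est.value > 0


class TestPrrChi2:
    def test_values(self):
        assert prr_estimate(T_STD).value == pytest.approx(10.0)
        assert chi2_statistic(T_STD).value == pytest.approx(
            oracle_chi2(10, 90, 100, 9900), rel=1e-12)

    def test_null_table(self):
        assert prr_estimate(T_NULL).value == pytest.approx(1.0, rel=1e-14)
        assert chi2_statistic(T_NULL).value == pytest.approx(0.0, abs=1e-9)

    def test_yates_smaller_than_uncorrected(self):
        assert chi2_statistic(T_STD, yates=True).value < chi2_statistic(T_STD).value

    def test_zero_margin_undefined(self):
        assert not prr_estimate(ContingencyTable(0, 0, 100, 9900)).defined

    def test_chi2_invariant_under_row_and_column_swap(self):
        t = ContingencyTable(7, 13, 29, 51)
        swapped = ContingencyTable(51, 29, 13, 7)  # both rows and columns flipped
        assert chi2_statistic(t).value == pytest.approx(
            chi2_statistic(swapped).value, rel=1e-12)


class TestRrr:
    def test_value(self):
        assert rrr_estimate(T_STD).value == pytest.approx(10 * 10100 / (100 * 110))

    def test_independence_is_one(self):
        assert rrr_estimate(T_NULL).value == pytest.approx(1.0, rel=1e-14)


tables = st.tuples(
    st.integers(1, 500), st.integers(1, 5000),
    st.integers(1, 5000), st.integers(1, 10_000_000),
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(tables)
def test_statistics_match_direct_formulas(cells):
    """Implementation agrees with independent direct-formula evaluation."""
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    ror, lo, hi = oracle_ror(a, b, c, d)
    est = ror_estimate(t)
    assert est.value == pytest.approx(ror, rel=1e-10)
    assert est.lo == pytest.approx(lo, rel=1e-10)
    assert est.hi == pytest.approx(hi, rel=1e-10)
    assert prr_estimate(t).value == pytest.approx(oracle_prr(a, b, c, d), rel=1e-10)
    assert chi2_statistic(t).value == pytest.approx(oracle_chi2(a, b, c, d), rel=1e-10)
    assert rrr_estimate(t).value == pytest.approx(oracle_rrr(a, b, c, d), rel=1e-10)
    assert bcpnn_ic(t).value == pytest.approx(
        math.log2(oracle_rrr(a, b, c, d)), rel=1e-10)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(st.integers(1, 50), st.integers(5000, 50000),
                 st.integers(1, 50), st.integers(5000, 500000)))
def test_ror_prr_agree_for_rare_events(cells):
    """ROR ~ PRR within 1% when the event is rare among both margins."""
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    if t.a / t.drug_margin >= 0.01 or t.a / t.event_margin >= 0.01:
        return
    assert ror_estimate(t).value == pytest.approx(prr_estimate(t).value, rel=0.01)


def test_monotone_in_a():
    prev_ror = prev_prr = prev_rrr = 0.0
    for a in (1, 5, 20, 80):
        t = ContingencyTable(a, 90, 100, 9900)
        assert ror_estimate(t).value > prev_ror
        assert prr_estimate(t).value > prev_prr
        assert rrr_estimate(t).value > prev_rrr
        prev_ror, prev_prr, prev_rrr = (ror_estimate(t).value,
                                        prr_estimate(t).value,
                                        rrr_estimate(t).value)


class TestMgps:
    def test_null_simulation_prior_concentrates_near_one(self):
        rng = np.random.default_rng(11)
        e = rng.uniform(5, 500, size=500)
        a = rng.poisson(e)  # lambda == 1 everywhere
        prior = mgps_fit_prior(a=a, e=e, seed=5)
        i = int(np.argmax(e))

        class Cell:
            def __init__(self, a, e):
                self.a, self._e = a, e

            @property
            def expected(self):
                return self._e

        est = ebgm_estimate(Cell(e[i], e[i]), prior=prior, mode="full")
        assert 0.9 <= est.value <= 1.1

    def test_single_component_recovery(self):
        # truth: w=1, lambda ~ Gamma(shape 2, rate 2), mean 1, var 0.5
        rng = np.random.default_rng(3)
        e = rng.uniform(10, 200, size=800)
        lam = rng.gamma(2.0, 0.5, size=800)
        a = rng.poisson(lam * e)
        prior = mgps_fit_prior(a=a, e=e, seed=9)
        comp_means = {prior.w: prior.alpha1 / prior.beta1,
                      1 - prior.w: prior.alpha2 / prior.beta2}
        heavy_w = max(comp_means)
        assert heavy_w >= 0.8
        assert comp_means[heavy_w] == pytest.approx(1.0, abs=0.2)

    def test_degenerate_single_cell_errors(self):
        with pytest.raises(MgpsFitError, match=">= 2 cells"):
            mgps_fit_prior(a=np.array([3.0]), e=np.array([1.0]))

    def test_full_mode_shrinkage_and_large_count_limit(self):
        # heterogeneous truth (lambda ~ Gamma(2, 2), mean 1) so the fitted
        # prior has genuine spread; on pure-null data empirical Bayes
        # legitimately collapses to a spike and the limit would not apply
        rng = np.random.default_rng(23)
        e = rng.uniform(5, 500, size=800)
        lam = rng.gamma(2.0, 0.5, size=800)
        a = rng.poisson(lam * e)
        prior = mgps_fit_prior(a=a, e=e, seed=5)

        class Cell:
            def __init__(self, a, e):
                self.a, self._e = a, e

            @property
            def expected(self):
                return self._e

        # a=1 cell with observed/expected = 10: strong shrinkage toward 1
        small = ebgm_estimate(Cell(1, 0.1), prior=prior, mode="full")
        assert 1.0 <= small.value < 10.0
        # large-count cell: the data swamp the prior
        big = ebgm_estimate(Cell(10_000, 2000), prior=prior, mode="full")
        assert big.value == pytest.approx(5.0, rel=0.05)
        assert small.lo <= small.value and big.lo <= big.value

    def test_simplified_mode_matches_rrr_with_lognormal_bound(self):
        est = ebgm_estimate(T_STD)
        rrr = oracle_rrr(10, 90, 100, 9900)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert est.value == pytest.approx(rrr, rel=1e-12)
        assert est.lo == pytest.approx(rrr * math.exp(-1.6448536269514722 * se), rel=1e-6)

    def test_full_mode_requires_prior(self):
        with pytest.raises(ValueError, match="[Pp]rior"):
            ebgm_estimate(T_STD, mode="full")


class TestBcpnn:
    def test_independence_gives_zero(self):
        assert bcpnn_ic(T_NULL).value == pytest.approx(0.0, abs=1e-12)

    def test_paper_compat_offset(self):
        est = bcpnn_ic(T_STD)
        assert est.value - est.lo == pytest.approx(1.67)

    def test_noren_zero_count_negative(self):
        t = ContingencyTable(0, 100, 50, 9850)
        est = bcpnn_ic(t, mode="noren")
        expected_ic = math.log2(0.5 / (t.expected + 0.5))
        assert est.value == pytest.approx(expected_ic, rel=1e-12)
        assert est.value < 0

    def test_noren_bound_below_point(self):
        est = bcpnn_ic(T_STD, mode="noren")
        assert est.lo < est.value


class TestClassifySignals:
    @pytest.mark.parametrize(
        "a, ror_lo, prr, chi2, eb05, ic025, expected",
        [
            # printed rows: oxycodone flags only ROR; pregabalin nothing;
            # dulaglutide ROR+PRR+MGPS but not BCPNN
            (1537, 1.02, 1.07, 7.06, 1.03, -1.57, (True, False, False, False)),
            (1054, 0.82, 0.87, 20.58, 0.83, -1.87, (False, False, False, False)),
            (1066, 2.22, 2.34, 819.90, 2.22, -0.44, (True, True, True, False)),
        ],
    )
    def test_printed_rows(self, a, ror_lo, prr, chi2, eb05, ic025, expected):
        f = classify_signals(a, ror_lo, prr, chi2, eb05, ic025)
        assert (f.ror, f.prr, f.mgps, f.bcpnn) == expected
        assert f.any == any(expected)

    def test_min_a_gates_ror_and_prr(self):
        f = classify_signals(2, 5.0, 5.0, 100.0, 5.0, 1.0)
        assert not f.ror and not f.prr
        assert f.mgps and f.bcpnn  # count gate applies only to ROR/PRR

    def test_undefined_statistics_never_flag(self):
        nan = float("nan")
        f = classify_signals(100, nan, nan, nan, nan, nan)
        assert not f.any

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            SignalCriteria(prr_ge=0.0)
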