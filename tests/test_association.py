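"""Pearson correlation, t-test p-values, and Fisher-z intervals."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from vulnindex import (
    UndefinedCorrelationError,
    ValidationError,
    correlate,
    correlation_p_value,
    correlation_table,
    fisher_ci,
    pearson_r,
)


def brute_force_r(x, y):
    """Loop-level covariance/variance oracle."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / math.sqrt(sxx * syy)


def paired_series(min_size=3, max_size=30):
    return arrays(
        float,
        st.shared(st.integers(min_value=min_size, max_value=max_size), key="n"),
        elements=st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
    )


class TestPearsonR:
    def test_perfect_linear_relationships(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == 1.0
        assert pearson_r(x, [-v for v in x]) == -1.0

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_and_short_series_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(ValidationError):
            pearson_r([1, 2], [3, 4])

    @given(paired_series(), paired_series())
    def test_matches_brute_force_oracle(self, x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        expected = brute_force_r(x.tolist(), y.tolist())
        if not math.isfinite(expected):
            return
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_fixture(self, district_fixture):
        r_ours = pearson_r(district_fixture["vi"], district_fixture["hospitals_per_100k"])
        r_scipy = stats.pearsonr(
            district_fixture["vi"], district_fixture["hospitals_per_100k"]
        ).statistic
        assert r_ours == pytest.approx(r_scipy, abs=1e-12)


class TestPValue:
    def test_null_and_exact_fit(self):
        assert correlation_p_value(0.0, 27) == 1.0
        assert correlation_p_value(1.0, 27) == 0.0
        assert correlation_p_value(-1.0, 10) == 0.0

    def test_published_values(self):
        assert round(correlation_p_value(0.414, 27), 3) == 0.032
        assert round(correlation_p_value(-0.583, 27), 3) == 0.001

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValidationError):
            correlation_p_value(1.5, 27)
        with pytest.raises(ValidationError):
            correlation_p_value(0.5, 2)


class TestFisherCI:
    def test_symmetric_about_zero(self):
        lower, upper = fisher_ci(0.0, 27)
        assert lower == pytest.approx(-upper)

    def test_published_intervals(self):
        lower, upper = fisher_ci(-0.583, 27)
        assert round(lower, 3) == -0.788
        assert round(upper, 3) == -0.261  # published -0.260; r itself is rounded
        lower, upper = fisher_ci(-0.750, 27)
        assert round(lower, 3) == -0.879
        assert round(upper, 3) == -0.517

    def test_interval_contains_r(self):
        for r in (-0.9, -0.3, 0.0, 0.42, 0.88):
            lower, upper = fisher_ci(r, 15)
            assert lower <= r <= upper

    def test_nesting_90_inside_95(self):
        for r in (-0.7, 0.0, 0.5):
            l90, u90 = fisher_ci(r, 27, level=0.90)
            l95, u95 = fisher_ci(r, 27, level=0.95)
            assert l95 < l90 and u90 < u95

    def test_degenerate_at_unit_correlation(self):
        with pytest.raises(UndefinedCorrelationError):
            fisher_ci(1.0, 27)

    @given(
        st.floats(min_value=-0.99, max_value=0.99),
        st.integers(min_value=5, max_value=100),
    )
    def test_sign_symmetry(self, r, n):
        lower, upper = fisher_ci(r, n)
        neg_lower, neg_upper = fisher_ci(-r, n)
        assert neg_lower == pytest.approx(-upper)
        assert neg_upper == pytest.approx(-lower)
        assert correlation_p_value(r, n) == pytest.approx(correlation_p_value(-r, n))


class TestCorrelationTable:
    def test_copy_of_index_gives_unit_correlation(self, district_fixture):
        frame = district_fixture.copy()
        frame["vi_copy"] = frame["vi"]
        results = correlation_table(frame, vi="vi", indicators=["vi_copy"])
        assert results[0].r == 1.0
        assert results[0].significant_at_0_05

    def test_constant_indicator_isolated(self, district_fixture):
        frame = district_fixture.copy()
        frame["flat"] = 7.0
        results = correlation_table(
            frame, vi="vi", indicators=["flat", "hospitals_per_100k"]
        )
        flat, hosp = results
        assert not flat.defined and math.isnan(flat.r)
        assert hosp.defined and hosp.r == pytest.approx(-0.583, abs=0.001)

    def test_negating_indicator_flips_r_and_ci(self, district_fixture):
        frame = district_fixture.copy()
        frame["neg"] = -frame["hospitals_per_100k"]
        pos, neg = correlation_table(
            frame, vi="vi", indicators=["hospitals_per_100k", "neg"]
        )
        assert neg.r == pytest.approx(-pos.r)
        assert neg.ci_lower == pytest.approx(-pos.ci_upper)
        assert neg.ci_upper == pytest.approx(-pos.ci_lower)
        assert neg.p_value == pytest.approx(pos.p_value)

    def test_vi_as_mapping_with_missing_district_rejected(self, district_fixture):
        vi = dict(zip(district_fixture["district"], district_fixture["vi"]))
        vi.pop("Raipur")
        with pytest.raises(ValidationError, match="Raipur"):
            correlation_table(district_fixture, vi=vi, indicators=["hospitals_per_100k"])

    def test_correlate_bundles_consistent_inference(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = correlate(x, y, "demo")
        assert res.ci_lower <= res.r <= res.ci_upper
        assert res.p_value == pytest.approx(correlation_p_value(res.r, 30))
        assert (res.ci_lower, res.ci_upper) == pytest.approx(fisher_ci(res.r, 30))
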