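"""Vulnerability-index construction: normalization, summation, ranking."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vulnindex import (
    DegenerateIndicatorError,
    IndicatorSpec,
    ValidationError,
    compute_index,
    normalize_indicator,
    rank_and_tertile,
    tertile_ranges,
)
from vulnindex.index import (
    LOWER_IS_MORE_VULNERABLE,
    group_sizes,
)

SPEC = IndicatorSpec("x")


def vi_tables(min_n=3, max_n=10):
    """Random district -> raw-value maps with a guaranteed spread."""
    return st.dictionaries(
        st.text(st.characters(categories=["Lu", "Ll"]), min_size=1, max_size=6),
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=min_n,
        max_size=max_n,
    ).filter(lambda d: max(d.values()) > min(d.values()))


class TestNormalize:
    def test_extremes_and_midpoint(self):
        norm = normalize_indicator({"a": 10.0, "b": 30.0, "c": 20.0}, SPEC)
        assert norm.values == {"a": 0.0, "b": 1.0, "c": 0.5}
        assert (norm.x_min, norm.x_max) == (10.0, 30.0)

    def test_lower_is_more_vulnerable_flips_orientation(self):
        spec = IndicatorSpec("income", orientation=LOWER_IS_MORE_VULNERABLE)
        norm = normalize_indicator({"poor": 100.0, "rich": 900.0, "mid": 500.0}, spec)
        assert norm.values["poor"] == 1.0
        assert norm.values["rich"] == 0.0
        assert norm.values["mid"] == 0.5

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateIndicatorError, match="constant"):
            normalize_indicator({"a": 5.0, "b": 5.0, "c": 5.0}, SPEC)

    def test_single_district_rejected(self):
        with pytest.raises(ValidationError):
            normalize_indicator({"a": 5.0}, SPEC)

    def test_bad_orientation_rejected(self):
        with pytest.raises(ValidationError, match="orientation"):
            IndicatorSpec("x", orientation="sideways")

    @given(vi_tables())
    def test_bounds_and_extremes_attained(self, raw):
        values = normalize_indicator(raw, SPEC).values
        assert all(0.0 <= v <= 1.0 for v in values.values())
        assert min(values.values()) == 0.0
        assert max(values.values()) == 1.0

    @given(
        vi_tables(),
        st.floats(min_value=0.01, max_value=100, allow_nan=False),
        st.floats(min_value=-50, max_value=50, allow_nan=False),
    )
    def test_affine_invariance(self, raw, a, b):
        # replacing Xi by a*Xi + b (a > 0) leaves every Yi unchanged
        base = normalize_indicator(raw, SPEC).values
        shifted = normalize_indicator({d: a * x + b for d, x in raw.items()}, SPEC).values
        for district in raw:
            assert base[district] == pytest.approx(shifted[district], abs=1e-9)


class TestComputeIndex:
    def _norms(self, *value_maps):
        return [
            normalize_indicator(vals, IndicatorSpec(f"i{k}"))
            for k, vals in enumerate(value_maps)
        ]

    def test_sum_of_normalized_values(self):
        # one district at the vulnerable extreme of both indicators
        vi = compute_index(self._norms({"a": 0, "b": 10}, {"a": 1, "b": 9}))
        assert vi["b"] == pytest.approx(2.0)
        assert vi["a"] == pytest.approx(0.0)

    def test_example_sum_four_point_seven(self):
        norms = self._norms({"a": 0, "b": 10}, {"a": 0, "b": 10})
        norms[0].values["b"] = 0.9  # fabricate mid-scale values directly
        norms[1].values["b"] = 0.8
        extra = self._norms({"a": 0, "b": 10}, {"a": 0, "b": 10}, {"a": 0, "b": 10})
        vi = compute_index(norms + extra)
        assert vi["b"] == pytest.approx(0.9 + 0.8 + 3 * 1.0) == pytest.approx(4.7)

    def test_mean_option_rescales_only(self):
        norms = self._norms({"a": 0, "b": 10, "c": 5}, {"a": 2, "b": 8, "c": 3})
        total = compute_index(norms)
        mean = compute_index(norms, mean=True)
        for d in total:
            assert mean[d] == pytest.approx(total[d] / 2)

    def test_mismatched_district_sets_listed(self):
        norms = self._norms({"a": 0, "b": 10}, {"a": 1, "c": 9})
        with pytest.raises(ValidationError, match=r"\['b', 'c'\]"):
            compute_index(norms)

    @given(st.data())
    def test_bound_conservation(self, data):
        raw = data.draw(vi_tables())
        k = data.draw(st.integers(min_value=1, max_value=5))
        norms = [normalize_indicator(raw, IndicatorSpec(f"i{j}")) for j in range(k)]
        vi = compute_index(norms)
        assert all(-1e-9 <= v <= k + 1e-9 for v in vi.values())


class TestRankAndTertile:
    def test_remainder_goes_to_most_vulnerable_group(self):
        scores = rank_and_tertile({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        by_group = {}
        for s in scores:
            by_group.setdefault(s.tertile, []).append(s.district_name)
        assert by_group == {"HVD": ["a", "b"], "MVD": ["c"], "LVD": ["d"]}

    def test_ranks_are_permutation_starting_at_most_vulnerable(self):
        scores = rank_and_tertile({"a": 1.0, "b": 3.0, "c": 2.0})
        assert sorted(s.rank for s in scores) == [1, 2, 3]
        assert next(s for s in scores if s.rank == 1).district_name == "b"

    def test_all_ties_split_by_name_order(self):
        scores = rank_and_tertile({n: 2.0 for n in "fedcba"})
        ordered = [s.district_name for s in scores]
        assert ordered == sorted(ordered)
        sizes = [sum(s.tertile == t for s in scores) for t in ("HVD", "MVD", "LVD")]
        assert sizes == [2, 2, 2]

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValidationError):
            rank_and_tertile({"a": 1.0, "b": 2.0})

    def test_generalizes_to_quintiles(self):
        scores = rank_and_tertile({f"d{i}": float(i) for i in range(11)}, n_groups=5)
        sizes = {}
        for s in scores:
            sizes[s.tertile] = sizes.get(s.tertile, 0) + 1
        assert sizes == {"G1": 3, "G2": 2, "G3": 2, "G4": 2, "G5": 2}

    @given(vi_tables(min_n=3, max_n=10))
    def test_matches_brute_force_sort_and_slice(self, raw):
        scores = {s.district_name: s for s in rank_and_tertile(raw)}
        # independent oracle: explicit sort then contiguous slices
        ordered = sorted(raw, key=lambda d: (-raw[d], d))
        n = len(ordered)
        sizes = group_sizes(n, 3)
        expected_groups = (
            [("HVD", d) for d in ordered[: sizes[0]]]
            + [("MVD", d) for d in ordered[sizes[0]: sizes[0] + sizes[1]]]
            + [("LVD", d) for d in ordered[sizes[0] + sizes[1]:]]
        )
        for rank, (group, district) in enumerate(expected_groups, start=1):
            assert scores[district].rank == rank
            assert scores[district].tertile == group

    @given(vi_tables(min_n=3, max_n=30))
    def test_group_sizes_differ_by_at_most_one(self, raw):
        scores = rank_and_tertile(raw)
        counts = [sum(s.tertile == t for s in scores) for t in ("HVD", "MVD", "LVD")]
        assert max(counts) - min(counts) <= 1

    def test_published_vi_column_ranges(self, district_fixture):
        vi = dict(zip(district_fixture["district"], district_fixture["vi"]))
        scores = rank_and_tertile(vi)
        ranges = tertile_ranges(scores)
        assert ranges["HVD"] == (4.9, 3.7)
        assert ranges["MVD"] == (3.6, 2.9)
        assert ranges["LVD"] == (2.9, 0.2)


class TestMonotonicity:
    def test_raising_oriented_value_never_lowers_vi(self):
        raw = {"a": 1.0, "b": 5.0, "c": 9.0, "d": 4.0}
        base = compute_index([normalize_indicator(raw, SPEC)])
        bumped = dict(raw, d=6.0)  # interior move, extremes unchanged
        after = compute_index([normalize_indicator(bumped, SPEC)])
        assert after["d"] >= base["d"]
        for other in "abc":
            assert after[other] == pytest.approx(base[other])
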