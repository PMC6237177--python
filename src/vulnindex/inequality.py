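"""Pairwise inequality measures between group-level rates.

Two classical measures: the rate *ratio* (relative inequality, group A
divided by group B) and the rate *difference* (absolute inequality,
A minus B). Reports compare the least-vulnerable and middle groups
against the most-vulnerable group (LVD:HVD and MVD:HVD), the
published convention. Ratios are computed on full-precision rates and
rounded only for display; a zero reference rate yields an explicitly
flagged undefined ratio, never a silent infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import UndefinedRateError, ValidationError
from .rates import RateRecord


@dataclass(frozen=True)
class InequalityMeasure:
    """One pairwise ratio or difference between two group rates."""

    indicator_name: str
    group_a: str
    group_b: str
    measure: str  # "ratio" | "difference"
    value: float  # NaN when undefined
    defined: bool = True


def pairwise_ratio(rate_a: float, rate_b: float) -> float:
    """Relative inequality: rate_a / rate_b."""
    if rate_a < 0 or rate_b < 0:
        raise ValidationError("rates must be non-negative")
    if rate_b == 0:
        raise UndefinedRateError("ratio undefined: reference rate is zero")
    return rate_a / rate_b


def pairwise_difference(rate_a: float, rate_b: float) -> float:
    """Absolute inequality: rate_a - rate_b."""
    return rate_a - rate_b


def compare_groups(
    rate_a: float, rate_b: float, indicator_name: str, group_a: str, group_b: str
) -> list[InequalityMeasure]:
    """Ratio and difference for one ordered group pair, with the ratio
    flagged undefined instead of raised when the reference rate is zero."""
    try:
        ratio = InequalityMeasure(
            indicator_name, group_a, group_b, "ratio", pairwise_ratio(rate_a, rate_b)
        )
    except UndefinedRateError:
        ratio = InequalityMeasure(
            indicator_name, group_a, group_b, "ratio", math.nan, defined=False
        )
    difference = InequalityMeasure(
        indicator_name, group_a, group_b, "difference",
        pairwise_difference(rate_a, rate_b),
    )
    return [ratio, difference]


def inequality_report(
    tertile_rates: Mapping[str, RateRecord] | Mapping[str, float],
    indicator_name: str | None = None,
    reference: str = "HVD",
    comparators: Sequence[str] = ("MVD", "LVD"),
) -> list[InequalityMeasure]:
    """LVD:HVD and MVD:HVD ratio and difference for one indicator.

    Accepts either the mapping of :class:`RateRecord` produced by
    ``tertile_aggregate`` or a plain tertile -> rate mapping. All three
    tertiles must be present.
    """
    rates: dict[str, float] = {}
    name = indicator_name
    for group, value in tertile_rates.items():
        if isinstance(value, RateRecord):
            rates[group] = value.rate_per_100k
            name = name or value.indicator_name
        else:
            rates[group] = float(value)
    name = name or "rate"

    needed = {reference, *comparators}
    missing = sorted(needed - set(rates))
    if missing:
        raise ValidationError(f"missing tertile rate(s): {missing}")

    measures: list[InequalityMeasure] = []
    for comparator in comparators:
        measures.extend(
            compare_groups(rates[comparator], rates[reference], name, comparator, reference)
        )
    return measures


def measures_to_frame(measures: Sequence[InequalityMeasure]):
    """Tidy DataFrame with a display column rounded to one decimal."""
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "indicator": m.indicator_name,
                "group_a": m.group_a,
                "group_b": m.group_b,
                "measure": m.measure,
                "value": m.value,
                "defined": m.defined,
            }
            for m in measures
        ]
    )
    frame["display"] = frame["value"].round(1)
    return frame
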