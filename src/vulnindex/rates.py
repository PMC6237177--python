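"""Insurance-scheme availability and utilization indicators.

All availability and utilization indicators are expressed per 100,000
*enrolled* persons — never per census population — so that insurance
coverage itself is held equal across comparison groups and the
indicators isolate the availability of services to those who could use
them. Claim amounts are reported in units of INR 100,000 (lakh) per
100,000 enrolled, matching the published scale.

Group-level (tertile or state) rates are pooled: numerators and
enrolled denominators are summed over member districts before
dividing. Pooling equals an enrolment-weighted mean of district rates
and keeps the state total consistent with the tertile decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .data_model import DistrictRecord, StateTable
from .errors import UndefinedRateError, ValidationError
from .index import VulnerabilityScore

PER = 100_000

#: numerator extractors, keyed by indicator name. Amounts are converted
#: from INR to INR lakh so rates land on the published unit.
NUMERATORS: dict[str, Callable[[DistrictRecord], float]] = {
    "hospitals_total": lambda r: r.hospitals_total,
    "hospitals_public": lambda r: r.hospitals_public,
    "hospitals_private": lambda r: r.hospitals_private,
    "claims_total_n": lambda r: r.claims_total_n,
    "claims_public_n": lambda r: r.claims_public_n,
    "claims_private_n": lambda r: r.claims_private_n,
    "claims_total_amount_lakh": lambda r: r.claims_total_amount / PER,
    "claims_public_amount_lakh": lambda r: r.claims_public_amount / PER,
    "claims_private_amount_lakh": lambda r: r.claims_private_amount / PER,
}

STATE_UNIT = "State"


@dataclass(frozen=True)
class RateRecord:
    """A numerator, its enrolled denominator, and the per-100k rate for
    one reporting unit (district, tertile, or state)."""

    unit_name: str
    indicator_name: str
    numerator: float
    denominator_enrolled: int
    rate_per_100k: float


def rate_per_100k(numerator: float, enrolled: int) -> float:
    """Rate per 100,000 enrolled persons."""
    if enrolled <= 0:
        raise UndefinedRateError(
            f"rate undefined: enrolled denominator is {enrolled}"
        )
    if numerator < 0:
        raise ValidationError(f"numerator must be non-negative, got {numerator}")
    return numerator / enrolled * PER


def enrolment_coverage(enrolled: int, census: int) -> float:
    """Enrolled persons (or households) as % of the census count.

    May exceed 100 — enrolment drives can outrun decade-old census
    projections — which callers should flag rather than reject.
    """
    if census <= 0:
        raise UndefinedRateError(f"coverage undefined: census count is {census}")
    return enrolled / census * 100.0


def sector_share(public_count: int, private_count: int) -> tuple[float, float]:
    """(public %, private %) of the empanelled total; sums to 100."""
    total = public_count + private_count
    if total <= 0:
        raise UndefinedRateError("sector share undefined: no hospitals empanelled")
    return public_count / total * 100.0, private_count / total * 100.0


def district_rate(record: DistrictRecord, indicator_name: str) -> RateRecord:
    """Per-100k rate of one indicator for a single district."""
    numerator = _numerator(indicator_name)(record)
    return RateRecord(
        unit_name=record.district_name,
        indicator_name=indicator_name,
        numerator=numerator,
        denominator_enrolled=record.enrolled_persons,
        rate_per_100k=rate_per_100k(numerator, record.enrolled_persons),
    )


def tertile_aggregate(
    table: StateTable,
    scores: Sequence[VulnerabilityScore],
    indicator_name: str,
    include_state_total: bool = True,
) -> dict[str, RateRecord]:
    """Pooled per-100k rates of one indicator by vulnerability group.

    Numerators and enrolled denominators are summed within each group;
    a ``"State"`` record pooling all districts is appended unless
    disabled. Every district in the table must carry a group
    assignment.
    """
    extract = _numerator(indicator_name)
    tertile_of = {s.district_name: s.tertile for s in scores}
    missing = [d for d in table.district_names if d not in tertile_of]
    if missing:
        raise ValidationError(f"districts without a tertile assignment: {missing}")

    sums: dict[str, list[float]] = {}
    for rec in table:
        group = tertile_of[rec.district_name]
        acc = sums.setdefault(group, [0.0, 0])
        acc[0] += extract(rec)
        acc[1] += rec.enrolled_persons

    out = {
        group: RateRecord(
            unit_name=group,
            indicator_name=indicator_name,
            numerator=num,
            denominator_enrolled=int(den),
            rate_per_100k=rate_per_100k(num, int(den)),
        )
        for group, (num, den) in sums.items()
    }
    if include_state_total:
        num = sum(acc[0] for acc in sums.values())
        den = int(sum(acc[1] for acc in sums.values()))
        out[STATE_UNIT] = RateRecord(
            unit_name=STATE_UNIT,
            indicator_name=indicator_name,
            numerator=num,
            denominator_enrolled=den,
            rate_per_100k=rate_per_100k(num, den),
        )
    return out


def rates_to_frame(records: Sequence[RateRecord]):
    """Tidy DataFrame of rate records."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "unit": r.unit_name,
                "indicator": r.indicator_name,
                "numerator": r.numerator,
                "denominator_enrolled": r.denominator_enrolled,
                "rate_per_100k": r.rate_per_100k,
            }
            for r in records
        ]
    )


def _numerator(indicator_name: str) -> Callable[[DistrictRecord], float]:
    try:
        return NUMERATORS[indicator_name]
    except KeyError:
        raise ValidationError(
            f"unknown indicator {indicator_name!r}; choose from {sorted(NUMERATORS)}"
        ) from None
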