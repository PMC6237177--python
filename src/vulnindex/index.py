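"""Composite vulnerability index: normalization, summation, ranking, tertiles.

The index follows the Human-Development-Index recipe: each raw
indicator is min-max normalized to [0, 1] across districts, oriented so
that 1 always means most vulnerable, and the normalized values are
combined with equal weights. The composite is reported as the *sum* of
the k normalized values (range [0, k]), matching the published VI scale
(maximum 4.9 on five indicators); the mean (sum / k) is available as an
option and yields identical ranks and tertiles.

Districts are ranked on the index (rank 1 = most vulnerable) and split
into groups of near-equal size — tertiles by default, generalizable to
any number of groups. Ties at full precision are broken by district
name ascending, a documented deterministic rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .data_model import StateTable
from .errors import DegenerateIndicatorError, ValidationError

HIGHER_IS_MORE_VULNERABLE = "higher_is_more_vulnerable"
LOWER_IS_MORE_VULNERABLE = "lower_is_more_vulnerable"
_ORIENTATIONS = (HIGHER_IS_MORE_VULNERABLE, LOWER_IS_MORE_VULNERABLE)


@dataclass(frozen=True)
class IndicatorSpec:
    """Identity and orientation of one raw vulnerability dimension.

    Orientation is always explicit, never inferred from the data: a
    silently flipped sign would invert every equity conclusion
    downstream.
    """

    name: str
    orientation: str = HIGHER_IS_MORE_VULNERABLE
    description: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENTATIONS:
            raise ValidationError(
                f"orientation must be one of {_ORIENTATIONS}, got {self.orientation!r}"
            )


#: The five-indicator set used for the Chhattisgarh analysis. Year of
#: district formation is oriented higher-is-more-vulnerable: newer
#: districts have had less time to build health and administrative
#: infrastructure.
DEFAULT_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("scst_pct", description="Scheduled Caste/Tribe population share (%)"),
    IndicatorSpec("unirrigated_pct", description="un-irrigated net sown area (%)"),
    IndicatorSpec("female_illiteracy_pct", description="female illiteracy (%)"),
    IndicatorSpec("rural_pct", description="rural population share (%)"),
    IndicatorSpec("formation_year", description="calendar year the district was formed"),
)


@dataclass
class NormalizedIndicator:
    """One indicator's oriented min-max normalization across districts.

    ``values`` maps district name to Yi = (Xi - Xmin) / (Xmax - Xmin)
    on the oriented series, so Yi = 0 at the least-vulnerable extreme
    and Yi = 1 at the most vulnerable.
    """

    spec: IndicatorSpec
    x_min: float
    x_max: float
    values: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class VulnerabilityScore:
    """Composite index value, rank and group label for one district."""

    district_name: str
    vi: float
    rank: int  # 1 = most vulnerable
    tertile: str


def normalize_indicator(
    raw: Mapping[str, float], spec: IndicatorSpec
) -> NormalizedIndicator:
    """Min-max normalize one raw series after orienting it.

    For ``lower_is_more_vulnerable`` indicators the series is negated
    before normalization, so 1 still marks the most vulnerable
    district. A constant series has no min-max scale and is rejected.
    """
    if len(raw) < 2:
        raise ValidationError(
            f"indicator {spec.name!r}: need at least 2 districts, got {len(raw)}"
        )
    sign = 1.0 if spec.orientation == HIGHER_IS_MORE_VULNERABLE else -1.0
    oriented = {d: sign * x for d, x in raw.items()}
    x_min = min(oriented.values())
    x_max = max(oriented.values())
    if x_max == x_min:
        raise DegenerateIndicatorError(
            f"indicator {spec.name!r} is constant across districts "
            f"(value {next(iter(raw.values()))}); min-max normalization undefined"
        )
    span = x_max - x_min
    values = {d: (x - x_min) / span for d, x in oriented.items()}
    return NormalizedIndicator(spec=spec, x_min=x_min, x_max=x_max, values=values)


def compute_index(
    normalized: Sequence[NormalizedIndicator], mean: bool = False
) -> dict[str, float]:
    """Combine normalized indicators into the composite index.

    The default is the unweighted sum (range [0, k]); ``mean=True``
    divides by k, which rescales the index without changing any rank
    or group assignment.
    """
    if not normalized:
        raise ValidationError("need at least one normalized indicator")
    reference = set(normalized[0].values)
    for norm in normalized[1:]:
        if set(norm.values) != reference:
            diff = sorted(set(norm.values) ^ reference)
            raise ValidationError(
                f"indicator {norm.spec.name!r} covers a different district set; "
                f"symmetric difference: {diff}"
            )
    k = len(normalized)
    vi = {
        d: sum(norm.values[d] for norm in normalized)
        for d in normalized[0].values
    }
    if mean:
        vi = {d: v / k for d, v in vi.items()}
    return vi


def group_sizes(n: int, n_groups: int) -> list[int]:
    """Near-equal group sizes, remainder allocated to the most
    vulnerable groups first (e.g. n=4, 3 groups -> [2, 1, 1])."""
    base, remainder = divmod(n, n_groups)
    return [base + (1 if g < remainder else 0) for g in range(n_groups)]


def default_group_labels(n_groups: int) -> list[str]:
    """HVD/MVD/LVD for tertiles; G1..Gk (most to least vulnerable)
    otherwise."""
    if n_groups == 3:
        return ["HVD", "MVD", "LVD"]
    return [f"G{i + 1}" for i in range(n_groups)]


def rank_and_tertile(
    vi_map: Mapping[str, float],
    n_groups: int = 3,
    labels: Sequence[str] | None = None,
) -> list[VulnerabilityScore]:
    """Rank districts by index (descending) and assign vulnerability groups.

    Sorting is on full-precision vi descending with ties broken by
    district name ascending; the sort is therefore a deterministic
    total order. Groups are as equal as possible, any remainder going
    to the most-vulnerable groups first.
    """
    n = len(vi_map)
    if n < n_groups:
        raise ValidationError(
            f"need at least {n_groups} districts for {n_groups} groups, got {n}"
        )
    if labels is None:
        labels = default_group_labels(n_groups)
    if len(labels) != n_groups:
        raise ValidationError(f"expected {n_groups} labels, got {len(labels)}")

    ordered = sorted(vi_map.items(), key=lambda item: (-item[1], item[0]))
    sizes = group_sizes(n, n_groups)
    scores: list[VulnerabilityScore] = []
    boundary = 0
    group = 0
    next_boundary = sizes[0]
    for rank, (district, vi) in enumerate(ordered, start=1):
        while rank > next_boundary:
            group += 1
            next_boundary += sizes[group]
        scores.append(
            VulnerabilityScore(district_name=district, vi=vi, rank=rank, tertile=labels[group])
        )
    return scores


def tertile_ranges(scores: Sequence[VulnerabilityScore]) -> dict[str, tuple[float, float]]:
    """Per-group (max vi, min vi), reported high-to-low as published."""
    ranges: dict[str, tuple[float, float]] = {}
    for score in scores:
        hi, lo = ranges.get(score.tertile, (-math.inf, math.inf))
        ranges[score.tertile] = (max(hi, score.vi), min(lo, score.vi))
    return ranges


def build_index(
    table: StateTable,
    specs: Sequence[IndicatorSpec] = DEFAULT_INDICATORS,
    n_groups: int = 3,
    mean: bool = False,
) -> list[VulnerabilityScore]:
    """Full index construction for a state table: normalize each
    indicator, sum, rank and group."""
    normalized = [
        normalize_indicator(table.indicator_series(spec.name), spec) for spec in specs
    ]
    vi = compute_index(normalized, mean=mean)
    return rank_and_tertile(vi, n_groups=n_groups)


def scores_to_frame(scores: Sequence[VulnerabilityScore]):
    """Tidy DataFrame of score records (district, vi, rank, tertile)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "district": s.district_name,
                "vi": s.vi,
                "rank": s.rank,
                "tertile": s.tertile,
            }
            for s in scores
        ]
    )
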