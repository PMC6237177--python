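"""Choropleth-ready GeoJSON export of vulnerability tertiles and rates.

Joins district boundary polygons to vulnerability scores and optional
per-district rates, producing a GeoJSON FeatureCollection whose
features carry ``tertile``, ``vi`` and rate properties. Geometry is
passed through untouched (no reprojection; WGS84 lon-lat assumed).
Class shading is deliberately encoded as data (the ``tertile``
property), never as colours — rendering belongs to downstream viewers.

The join key is the district name, compared case-insensitively after
whitespace normalization. Boundary features that fail to join are
reported, not dropped silently; a join that matches nothing is an
error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ValidationError
from .index import VulnerabilityScore
from .rates import RateRecord


@dataclass
class JoinReport:
    """Outcome of matching boundary features to scored districts."""

    joined: list[str] = field(default_factory=list)
    unmatched_boundaries: list[str] = field(default_factory=list)
    unmatched_scores: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.unmatched_boundaries and not self.unmatched_scores


def normalize_name(name: str) -> str:
    """Canonical join key: casefolded, inner whitespace collapsed."""
    return " ".join(str(name).split()).casefold()


def build_choropleth(
    boundaries: dict | str | Path,
    scores: Sequence[VulnerabilityScore],
    rates: Sequence[RateRecord] = (),
    name_property: str = "district",
) -> tuple[dict, JoinReport]:
    """Attach tertile, vi and rate properties to district polygons.

    ``boundaries`` is a GeoJSON FeatureCollection (dict, or path to a
    file); each feature must carry the district name under
    ``name_property``. Returns the enriched FeatureCollection and a
    :class:`JoinReport`. Zero joined features is an error; a partial
    join is reported but not fatal.
    """
    if not scores:
        raise ValidationError("no vulnerability scores supplied")
    if isinstance(boundaries, (str, Path)):
        with open(boundaries, encoding="utf-8") as fh:
            boundaries = json.load(fh)
    if boundaries.get("type") != "FeatureCollection":
        raise ValidationError("boundaries must be a GeoJSON FeatureCollection")

    by_district: dict[str, dict] = {}
    for score in scores:
        key = normalize_name(score.district_name)
        by_district[key] = {"district": score.district_name,
                            "vi": score.vi, "rank": score.rank,
                            "tertile": score.tertile}
    for rate in rates:
        key = normalize_name(rate.unit_name)
        if key in by_district:
            by_district[key][rate.indicator_name + "_per_100k"] = rate.rate_per_100k

    report = JoinReport()
    features = []
    matched_keys: set[str] = set()
    for feature in boundaries.get("features", []):
        props = dict(feature.get("properties") or {})
        raw_name = props.get(name_property)
        key = normalize_name(raw_name) if raw_name is not None else None
        if key in by_district:
            props.update(by_district[key])
            matched_keys.add(key)
            report.joined.append(by_district[key]["district"])
            features.append(
                {"type": "Feature", "geometry": feature.get("geometry"),
                 "properties": props}
            )
        else:
            report.unmatched_boundaries.append(str(raw_name))
    report.unmatched_scores = sorted(
        by_district[k]["district"] for k in set(by_district) - matched_keys
    )

    if not features:
        raise ValidationError(
            "no boundary feature matched any scored district "
            f"(boundary names: {report.unmatched_boundaries[:5]} ...)"
        )
    return {"type": "FeatureCollection", "features": features}, report


def write_geojson(layer: dict, path: str | Path) -> Path:
    """Write a FeatureCollection; round-trips property values exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(layer, indent=2), encoding="utf-8")
    return path
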