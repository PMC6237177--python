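"""End-to-end orchestration: index -> tertiles -> rates -> inequality
-> correlations (-> map), with file outputs and stage logging.

Two modes share the same downstream stages. *Table mode* starts from a
raw district table (user CSV or the synthetic generator) and builds
the index from raw indicators. *Reproduction mode* starts from the
packaged published district table, whose index values are the printed
ones (raw indicators were never published), and reproduces the
published correlation and inequality tables.

Each stage consumes only values produced by prior stages; rerunning on
identical inputs overwrites outputs with identical content.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import datasets
from .association import correlation_table, correlations_to_frame
from .data_model import StateTable, read_state_table
from .errors import ValidationError
from .geo import build_choropleth, write_geojson
from .index import (
    DEFAULT_INDICATORS,
    IndicatorSpec,
    build_index,
    scores_to_frame,
    tertile_ranges,
)
from .inequality import inequality_report, measures_to_frame
from .rates import NUMERATORS, district_rate, rates_to_frame, tertile_aggregate

log = logging.getLogger("vulnindex")

#: Indicators whose tertile rates and ratios every report includes.
REPORT_INDICATORS = tuple(NUMERATORS)


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    input_path: str | None = None          # raw district CSV
    fixture: str | None = None             # "district_table" for reproduction mode
    boundaries_path: str | None = None     # optional GeoJSON to join
    indicators: list[dict] = field(default_factory=list)  # [{name, orientation}]
    n_groups: int = 3
    outdir: str = "vulnindex_out"
    formats: list[str] = field(default_factory=lambda: ["csv"])

    _FIELDS = (
        "input_path", "fixture", "boundaries_path", "indicators",
        "n_groups", "outdir", "formats",
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = sorted(set(raw) - set(cls._FIELDS))
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        config = cls(**raw)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if (self.input_path is None) == (self.fixture is None):
            raise ValidationError("exactly one of input_path / fixture is required")
        if self.n_groups < 2:
            raise ValidationError("n_groups must be >= 2")
        bad = sorted(set(self.formats) - {"csv", "json"})
        if bad:
            raise ValidationError(f"unknown output formats: {bad}")
        for spec in self.indicator_specs():
            pass  # IndicatorSpec construction validates orientation

    def indicator_specs(self) -> tuple[IndicatorSpec, ...]:
        if not self.indicators:
            return DEFAULT_INDICATORS
        return tuple(IndicatorSpec(**entry) for entry in self.indicators)


def analyze_table(
    table: StateTable,
    specs: Sequence[IndicatorSpec] = DEFAULT_INDICATORS,
    n_groups: int = 3,
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage on a raw district table.

    Returns tidy frames: ``scores`` (vi, rank, tertile), ``rates``
    (district + tertile + state pooled rates for every indicator),
    ``inequality`` (MVD:HVD and LVD:HVD ratio and difference), and
    ``correlations`` (VI vs each per-100k indicator).
    """
    scores = build_index(table, specs, n_groups=n_groups)
    log.info("index: scored %d districts on %d indicators", len(scores), len(specs))

    rate_records = []
    tertile_rates: dict[str, dict] = {}
    for indicator in REPORT_INDICATORS:
        rate_records.extend(district_rate(rec, indicator) for rec in table)
        pooled = tertile_aggregate(table, scores, indicator)
        tertile_rates[indicator] = pooled
        rate_records.extend(pooled.values())
    log.info("rates: %d rate records over %d indicators",
             len(rate_records), len(REPORT_INDICATORS))

    measures = []
    if n_groups == 3:
        for indicator, pooled in tertile_rates.items():
            groups = {g: r for g, r in pooled.items() if g != "State"}
            measures.extend(inequality_report(groups, indicator))
        log.info("inequality: %d pairwise measures", len(measures))

    frame = table.to_frame().copy()
    vi = {s.district_name: s.vi for s in scores}
    rate_cols = []
    for indicator in REPORT_INDICATORS:
        col = indicator + "_per_100k"
        frame[col] = [
            district_rate(rec, indicator).rate_per_100k for rec in table
        ]
        rate_cols.append(col)
    results = correlation_table(frame, vi=vi, indicators=rate_cols)
    log.info("association: %d correlations (n = %d districts)",
             len(results), len(table))

    return {
        "scores": scores_to_frame(scores),
        "rates": rates_to_frame(rate_records),
        "inequality": measures_to_frame(measures) if measures else pd.DataFrame(),
        "correlations": correlations_to_frame(results),
        "_scores_objects": scores,  # for optional geo stage
        "_rate_objects": rate_records,
    }


def reproduce_published() -> dict[str, pd.DataFrame]:
    """Reproduce the published analysis from the packaged fixtures.

    Re-ranks the printed VI column into tertiles, recomputes the
    Pearson correlation table from printed VI and rates, and recomputes
    the LVD:HVD / MVD:HVD ratio columns from printed tertile rates.
    """
    from .index import rank_and_tertile

    districts = datasets.load_chhattisgarh("district_table")
    tertiles = datasets.load_chhattisgarh("tertile_table")

    vi_map = dict(zip(districts["district"], districts["vi"]))
    scores = rank_and_tertile(vi_map)
    ranges = tertile_ranges(scores)
    log.info("index: re-ranked %d districts; tertile VI ranges %s",
             len(scores), ranges)

    results = correlation_table(
        districts, vi="vi", indicators=datasets.district_rate_columns()
    )

    measures = []
    rate_rows = tertiles[tertiles["indicator"].str.endswith("_per_100k")]
    for _, row in rate_rows.iterrows():
        groups = {g: float(row[g]) for g in ("HVD", "MVD", "LVD")}
        measures.extend(inequality_report(groups, row["indicator"]))
    log.info("inequality: recomputed ratio/difference for %d indicators",
             len(rate_rows))

    ranges_frame = pd.DataFrame(
        [{"tertile": t, "vi_max": hi, "vi_min": lo} for t, (hi, lo) in ranges.items()]
    )
    return {
        "scores": scores_to_frame(scores),
        "tertile_ranges": ranges_frame,
        "correlations": correlations_to_frame(results),
        "inequality": measures_to_frame(measures),
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured pipeline and write its report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.fixture is not None:
        if config.fixture != "district_table":
            raise ValidationError(
                f"fixture mode supports 'district_table', got {config.fixture!r}"
            )
        frames = reproduce_published()
    else:
        specs = config.indicator_specs()
        table = read_state_table(config.input_path, [s.name for s in specs])
        frames = analyze_table(table, specs, n_groups=config.n_groups)
        if config.boundaries_path:
            layer, report = build_choropleth(
                config.boundaries_path,
                frames["_scores_objects"],
                frames["_rate_objects"],
            )
            write_geojson(layer, outdir / "map.geojson")
            if not report.complete:
                log.warning("map: partial join; unmatched boundaries %s, "
                            "unmatched districts %s",
                            report.unmatched_boundaries, report.unmatched_scores)

    written: dict[str, Path] = {}
    for name, frame in frames.items():
        if name.startswith("_") or frame.empty:
            continue
        if "csv" in config.formats:
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written[name] = path
        if "json" in config.formats:
            path = outdir / f"{name}.json"
            path.write_text(
                json.dumps(frame.to_dict(orient="records"), indent=2, default=str),
                encoding="utf-8",
            )
            written.setdefault(name, path)
    if (outdir / "map.geojson").exists():
        written["map"] = outdir / "map.geojson"
    log.info("pipeline: wrote %s", sorted(p.name for p in written.values()))
    return written
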