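"""District-level data model and delimited-table input/output.

A :class:`DistrictRecord` carries one district's raw socio-economic
indicators (percentages, or a calendar year for district formation)
together with its insurance-scheme administrative counts: enrolment,
census denominators, empanelled hospitals by sector, and claim counts
and INR amounts by sector. A :class:`StateTable` is an ordered,
validated collection of such records for one state.

Tables are exchanged as UTF-8, comma-delimited CSV with a mandatory
header and '.' decimal separator. Missing values are never imputed:
small administrative tables are expected to be complete, and a silent
fill would corrupt downstream equity estimates, so any empty or
non-numeric cell fails fast with the offending row and column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import SchemaError, TableParseError, ValidationError

#: Scheme-count columns every state table must carry, in canonical order.
SCHEME_COLUMNS: tuple[str, ...] = (
    "enrolled_persons",
    "enrolled_households",
    "census_population",
    "census_households",
    "hospitals_public",
    "hospitals_private",
    "claims_public_n",
    "claims_private_n",
    "claims_public_amount",
    "claims_private_amount",
)

#: Column holding the district identifier.
NAME_COLUMN = "district"

#: Minimum number of districts: tertile grouping needs at least three.
MIN_DISTRICTS = 3


@dataclass
class DistrictRecord:
    """One district's raw indicators and insurance-scheme counts.

    Parameters
    ----------
    district_name
        Unique district identifier within its table.
    raw_indicators
        Mapping of indicator name to raw value. Proportions are
        percentages in [0, 100]; year of district formation is a
        calendar year.
    enrolled_persons, enrolled_households
        Persons / households enrolled in the insurance scheme.
    census_population, census_households
        2011-census denominators.
    hospitals_public, hospitals_private
        Empanelled hospitals by sector.
    claims_public_n, claims_private_n
        Claim counts by the sector of the hospital filing the claim
        (claims are attributed to the hospital's district, not the
        patient's home district).
    claims_public_amount, claims_private_amount
        Claim amounts in INR by sector.
    """

    district_name: str
    raw_indicators: dict[str, float] = field(default_factory=dict)
    enrolled_persons: int = 0
    enrolled_households: int = 0
    census_population: int = 0
    census_households: int = 0
    hospitals_public: int = 0
    hospitals_private: int = 0
    claims_public_n: int = 0
    claims_private_n: int = 0
    claims_public_amount: float = 0.0
    claims_private_amount: float = 0.0

    def __post_init__(self) -> None:
        if not self.district_name or not str(self.district_name).strip():
            raise ValidationError("district_name must be non-empty")
        for col in SCHEME_COLUMNS:
            value = getattr(self, col)
            if value < 0:
                raise ValidationError(
                    f"{self.district_name}: {col} must be non-negative, got {value}"
                )

    # Derived totals used throughout the rate computations.
    @property
    def hospitals_total(self) -> int:
        return self.hospitals_public + self.hospitals_private

    @property
    def claims_total_n(self) -> int:
        return self.claims_public_n + self.claims_private_n

    @property
    def claims_total_amount(self) -> float:
        return self.claims_public_amount + self.claims_private_amount


@dataclass
class StateTable:
    """Ordered, validated collection of district records for one state."""

    districts: list[DistrictRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.districts) < MIN_DISTRICTS:
            raise ValidationError(
                f"a state table needs at least {MIN_DISTRICTS} districts for "
                f"tertile grouping, got {len(self.districts)}"
            )
        seen: set[str] = set()
        for rec in self.districts:
            if rec.district_name in seen:
                raise ValidationError(f"duplicate district {rec.district_name!r}")
            seen.add(rec.district_name)

    def __len__(self) -> int:
        return len(self.districts)

    def __iter__(self):
        return iter(self.districts)

    @property
    def district_names(self) -> list[str]:
        return [rec.district_name for rec in self.districts]

    def record(self, name: str) -> DistrictRecord:
        for rec in self.districts:
            if rec.district_name == name:
                return rec
        raise KeyError(name)

    def indicator_series(self, indicator: str) -> dict[str, float]:
        """Raw values of one indicator keyed by district, in table order."""
        try:
            return {r.district_name: r.raw_indicators[indicator] for r in self.districts}
        except KeyError as exc:
            raise SchemaError(f"indicator {exc.args[0]!r} missing from a record") from None

    @property
    def indicator_names(self) -> list[str]:
        return list(self.districts[0].raw_indicators)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame: name, indicator columns, scheme counts."""
        rows = []
        for rec in self.districts:
            row: dict[str, object] = {NAME_COLUMN: rec.district_name}
            row.update(rec.raw_indicators)
            for col in SCHEME_COLUMNS:
                row[col] = getattr(rec, col)
            rows.append(row)
        return pd.DataFrame(rows)


def _coerce_cell(raw: object, row_label: str, column: str) -> float:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        raise TableParseError(f"empty cell at row {row_label!r}, column {column!r}")
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise TableParseError(
            f"non-numeric value {raw!r} at row {row_label!r}, column {column!r}"
        ) from None


def read_state_table(
    path: str | Path,
    schema: Sequence[str],
    provenance: str = "",
) -> StateTable:
    """Read a district CSV into a validated :class:`StateTable`.

    ``schema`` names the raw indicator columns the active index
    configuration requires; a file missing any of them (or any scheme
    count column) is rejected with the column named. Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str)
    return state_table_from_frame(frame, schema, provenance or f"read from {path}")


def state_table_from_frame(
    frame: pd.DataFrame,
    schema: Sequence[str],
    provenance: str = "",
) -> StateTable:
    """Validate a raw (string-typed) DataFrame into a :class:`StateTable`."""
    required = [NAME_COLUMN, *schema, *SCHEME_COLUMNS]
    for column in required:
        if column not in frame.columns:
            raise SchemaError(f"missing required column {column!r}")

    records = []
    for _, row in frame.iterrows():
        name = str(row[NAME_COLUMN]).strip()
        indicators = {
            ind: _coerce_cell(row[ind], name, ind) for ind in schema
        }
        counts = {col: _coerce_cell(row[col], name, col) for col in SCHEME_COLUMNS}
        int_cols = [c for c in SCHEME_COLUMNS if not c.endswith("amount")]
        kwargs: dict[str, object] = {c: int(round(counts[c])) for c in int_cols}
        kwargs.update({c: counts[c] for c in SCHEME_COLUMNS if c.endswith("amount")})
        records.append(
            DistrictRecord(district_name=name, raw_indicators=indicators, **kwargs)
        )
    return StateTable(districts=records, provenance=provenance)


def write_state_table(table: StateTable, path: str | Path) -> Path:
    """Write a state table to CSV; a read back reproduces every field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False)
    return path


def table_to_json(table: StateTable) -> list[dict]:
    """JSON-serializable representation (one object per district)."""
    return table.to_frame().to_dict(orient="records")
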