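"""Packaged published data for the Chhattisgarh 2015-16 analysis.

Two fixtures ship with the package, transcribed from the published
district and tertile tables of the Chhattisgarh universal health
insurance study (financial year 2015-16, 27 districts):

``district_table``
    Per-district composite vulnerability index (VI), tertile label, and
    the six per-100,000-enrolled rates (empanelled hospitals and claim
    counts, total / public / private). Values carry the published
    one-decimal precision; the raw socio-economic indicator values
    behind the VI were released only in supplementary files that are
    not publicly archived, so raw indicators are deliberately absent
    and the VI cannot be recomputed from this fixture — analyses start
    from the printed VI column.

``tertile_table``
    Pooled tertile-level rates, counts and published LVD:HVD / MVD:HVD
    ratio columns, plus tertile enrolment coverage.

State-level totals that appear in the published text (not the tables)
are exposed as module constants.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA_PACKAGE = "vulnindex.data"

#: State totals for 2015-16 as published.
STATE_ENROLLED_PERSONS = 12_500_000
STATE_ENROLLED_HOUSEHOLDS = 4_100_000
STATE_HOSPITALS_TOTAL = 735
STATE_HOSPITALS_PUBLIC = 273
STATE_HOSPITALS_PRIVATE = 462

#: Tertile labels in decreasing-vulnerability order.
TERTILE_LABELS = ("HVD", "MVD", "LVD")

_FIXTURES = {
    "district_table": "chhattisgarh_districts.csv",
    "tertile_table": "chhattisgarh_tertiles.csv",
}


def load_chhattisgarh(which: str = "district_table") -> pd.DataFrame:
    """Load one of the packaged Chhattisgarh fixtures.

    Parameters
    ----------
    which
        ``"district_table"`` (27 rows: district, vi, tertile, six
        per-100k rate columns) or ``"tertile_table"`` (one row per
        indicator: HVD/MVD/LVD/state values and published ratio
        columns).
    """
    try:
        filename = _FIXTURES[which]
    except KeyError:
        raise ValueError(
            f"unknown fixture {which!r}; choose from {sorted(_FIXTURES)}"
        ) from None
    ref = resources.files(_DATA_PACKAGE).joinpath(filename)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def district_rate_columns() -> list[str]:
    """Rate columns of the district fixture, in published order."""
    return [
        "hospitals_per_100k",
        "public_hospitals_per_100k",
        "private_hospitals_per_100k",
        "claims_per_100k",
        "public_claims_per_100k",
        "private_claims_per_100k",
    ]
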