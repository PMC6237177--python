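"""Pearson correlation between the vulnerability index and scheme
indicators, with t-test p-values and Fisher-z confidence intervals.

The correlation is the plain product-moment coefficient across
districts. Its two-sided p-value comes from t = r sqrt(n-2) /
sqrt(1-r^2) on n-2 degrees of freedom, and the confidence interval
from the Fisher z-transform, tanh(atanh(r) +/- z_crit / sqrt(n-3)) —
the standard bivariate-normal constructions, which reproduce the
published intervals and p-values for this analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with inference for one (index, indicator) pair."""

    indicator_name: str
    r: float
    n: int
    p_value: float
    ci_lower: float
    ci_upper: float
    significant_at_0_05: bool
    defined: bool = True


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    Computed directly from centred sums; clipped to [-1, 1] to absorb
    floating-point overshoot on exactly collinear inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    return max(-1.0, min(1.0, r))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for H0: rho = 0, via the exact t distribution.

    |r| = 1 is an exact linear fit and returns p = 0.
    """
    _check_r_n(r, n, min_n=3)
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a correlation."""
    _check_r_n(r, n, min_n=4)
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    if abs(r) == 1.0:
        raise UndefinedCorrelationError(
            "confidence interval degenerate at |r| = 1"
        )
    z = math.atanh(r)
    half_width = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half_width), math.tanh(z + half_width)


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    indicator_name: str = "",
    level: float = 0.95,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Full inference for one pair: r, p, CI, significance flag."""
    r = pearson_r(x, y)
    n = len(x)
    p = correlation_p_value(r, n)
    if abs(r) == 1.0:
        lower = upper = r
    else:
        lower, upper = fisher_ci(r, n, level=level)
    return CorrelationResult(
        indicator_name=indicator_name,
        r=r,
        n=n,
        p_value=p,
        ci_lower=lower,
        ci_upper=upper,
        significant_at_0_05=p < alpha,
    )


def correlation_table(
    frame: pd.DataFrame,
    vi: Mapping[str, float] | str = "vi",
    indicators: Sequence[str] | None = None,
    district_column: str = "district",
) -> list[CorrelationResult]:
    """Correlate the vulnerability index against each indicator column.

    ``vi`` is either the name of the index column in ``frame`` or a
    district -> index mapping covering every district in the frame.
    An indicator that is constant across districts yields a flagged
    undefined row; remaining rows are still computed.
    """
    if isinstance(vi, str):
        if vi not in frame.columns:
            raise ValidationError(f"index column {vi!r} not in frame")
        vi_values = frame[vi].to_numpy(dtype=float)
    else:
        missing = [d for d in frame[district_column] if d not in vi]
        if missing:
            raise ValidationError(f"districts missing from the index map: {missing}")
        vi_values = np.array([vi[d] for d in frame[district_column]], dtype=float)

    if indicators is None:
        reserved = {district_column, vi if isinstance(vi, str) else None, "tertile"}
        indicators = [c for c in frame.columns if c not in reserved]

    results: list[CorrelationResult] = []
    for name in indicators:
        if name not in frame.columns:
            raise ValidationError(f"indicator column {name!r} not in frame")
        try:
            results.append(correlate(vi_values, frame[name].to_numpy(dtype=float), name))
        except UndefinedCorrelationError:
            results.append(
                CorrelationResult(
                    indicator_name=name, r=math.nan, n=len(frame),
                    p_value=math.nan, ci_lower=math.nan, ci_upper=math.nan,
                    significant_at_0_05=False, defined=False,
                )
            )
    return results


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Published-style table: indicator, r, p, CI limits, star."""
    return pd.DataFrame(
        [
            {
                "indicator": res.indicator_name,
                "r": res.r,
                "n": res.n,
                "p_value": res.p_value,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "significant": "*" if res.significant_at_0_05 else "",
            }
            for res in results
        ]
    )


def _check_r_n(r: float, n: int, min_n: int) -> None:
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r}")
    if n < min_n:
        raise ValidationError(f"need n >= {min_n}, got {n}")
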