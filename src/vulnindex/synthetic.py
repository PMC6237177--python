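"""Synthetic state panels with a centre-periphery vulnerability gradient.

The generator emulates the structure the equity analysis assumes: an
abstract state whose districts sit on a plane around a central
"capital", with latent vulnerability rising with distance from the
centre. Five raw socio-economic indicators are monotone noisy
transforms of the latent vulnerability; enrolment follows a logistic
coverage model (a positive ``coverage_slope`` reproduces pro-poor
enrolment); empanelled hospital counts are Poisson with a log-linear
vulnerability effect per sector (``beta_private`` strongly negative and
``beta_public`` near zero reproduce the published pattern of private
hospitals avoiding vulnerable districts while public ones are flat);
claims are Poisson per hospital and amounts multiply claims by a noisy
per-claim cost.

Every generated table passes :class:`~vulnindex.data_model.StateTable`
validation, and generation is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .association import correlation_table
from .data_model import DistrictRecord, StateTable
from .errors import ValidationError
from .index import DEFAULT_INDICATORS, build_index
from .rates import tertile_aggregate


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic state generator.

    Baseline magnitudes are set to the observed scale of a large Indian
    state: ~0.95 M census population per district, ~50% enrolment,
    2.2 public and 3.7 private empanelled hospitals per 100,000
    enrolled, 650/1,100 claims per public/private hospital per year,
    mean claim costs 3,700/6,000 INR (public/private).
    """

    n_districts: int = 27
    seed: int = 0
    gradient_strength: float = 1.0   # latent vulnerability per unit distance
    vuln_noise_sd: float = 0.3       # non-spatial vulnerability noise
    beta_private: float = -1.0       # log-linear VI effect on private density
    beta_public: float = 0.0         # log-linear VI effect on public density
    base_public_per_100k: float = 2.2
    base_private_per_100k: float = 3.7
    claims_per_public_hospital: float = 650.0
    claims_per_private_hospital: float = 1100.0
    mean_cost_public: float = 3_700.0    # INR per claim
    mean_cost_private: float = 6_000.0
    enrolment_base: float = 0.0      # logit of coverage at mean vulnerability
    coverage_slope: float = 0.1      # logit slope on standardized vulnerability
    census_mean: int = 950_000
    census_log_sd: float = 0.4
    persons_per_household: float = 4.8

    def validate(self) -> None:
        if self.n_districts < 3:
            raise ValidationError(f"need >= 3 districts, got {self.n_districts}")
        if self.gradient_strength < 0:
            raise ValidationError("gradient_strength must be >= 0")
        positive = (
            "base_public_per_100k", "base_private_per_100k",
            "claims_per_public_hospital", "claims_per_private_hospital",
            "mean_cost_public", "mean_cost_private",
            "census_mean", "persons_per_household",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("vuln_noise_sd", "census_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name, value in asdict(self).items():
            if isinstance(value, float) and not math.isfinite(value):
                raise ValidationError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Latent state realized alongside a generated table."""

    config: GeneratorConfig
    latent_vulnerability: dict[str, float]
    positions: dict[str, tuple[float, float]]


def _district_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"D{i + 1:0{width}d}" for i in range(n)]


def _grid_positions(n: int) -> np.ndarray:
    """Centres of the first n cells of a near-square grid spanning
    [-1, 1]^2; the grid centre plays the role of the state capital."""
    ncol = math.ceil(math.sqrt(n))
    nrow = math.ceil(n / ncol)
    xs = (np.arange(ncol) + 0.5) / ncol * 2 - 1
    ys = (np.arange(nrow) + 0.5) / nrow * 2 - 1
    pts = [(xs[i % ncol], ys[i // ncol]) for i in range(n)]
    return np.array(pts)


def generate_state(config: GeneratorConfig) -> tuple[StateTable, GroundTruth]:
    """Draw one synthetic state panel; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_districts
    names = _district_names(n)
    positions = _grid_positions(n)

    distance = np.hypot(positions[:, 0], positions[:, 1])
    latent = config.gradient_strength * distance + rng.normal(0, config.vuln_noise_sd, n)
    spread = latent.std()
    z = (latent - latent.mean()) / spread if spread > 0 else np.zeros(n)

    # Five monotone noisy transforms of latent vulnerability, on the
    # scales of the real indicators (percentages; formation year).
    scst = np.clip(35 + 18 * z + rng.normal(0, 5, n), 0, 100)
    unirrigated = np.clip(65 + 12 * z + rng.normal(0, 6, n), 0, 100)
    illiteracy = np.clip(40 + 10 * z + rng.normal(0, 4, n), 0, 100)
    rural = np.clip(77 + 10 * z + rng.normal(0, 5, n), 0, 100)
    formation = np.clip(
        np.rint(1985 + 9 * z + rng.normal(0, 6, n)), 1948, 2012
    )

    census = np.maximum(
        np.rint(rng.lognormal(math.log(config.census_mean), config.census_log_sd, n)),
        1_000,
    ).astype(int)
    coverage = 1.0 / (1.0 + np.exp(-(config.enrolment_base + config.coverage_slope * z)))
    enrolled = rng.binomial(census, coverage)
    enrolled = np.maximum(enrolled, 1)  # a zero-enrolment district has no rates

    exposure = enrolled / 100_000.0
    lam_public = exposure * config.base_public_per_100k * np.exp(config.beta_public * z)
    lam_private = exposure * config.base_private_per_100k * np.exp(config.beta_private * z)
    hosp_public = rng.poisson(lam_public)
    hosp_private = rng.poisson(lam_private)

    claims_public = rng.poisson(hosp_public * config.claims_per_public_hospital)
    claims_private = rng.poisson(hosp_private * config.claims_per_private_hospital)
    cost_sd = 0.2
    cost_public = config.mean_cost_public * rng.lognormal(-cost_sd**2 / 2, cost_sd, n)
    cost_private = config.mean_cost_private * rng.lognormal(-cost_sd**2 / 2, cost_sd, n)

    records = []
    for i, name in enumerate(names):
        records.append(
            DistrictRecord(
                district_name=name,
                raw_indicators={
                    "scst_pct": float(scst[i]),
                    "unirrigated_pct": float(unirrigated[i]),
                    "female_illiteracy_pct": float(illiteracy[i]),
                    "rural_pct": float(rural[i]),
                    "formation_year": float(formation[i]),
                },
                enrolled_persons=int(enrolled[i]),
                enrolled_households=int(round(enrolled[i] / config.persons_per_household)),
                census_population=int(census[i]),
                census_households=int(round(census[i] / config.persons_per_household)),
                hospitals_public=int(hosp_public[i]),
                hospitals_private=int(hosp_private[i]),
                claims_public_n=int(claims_public[i]),
                claims_private_n=int(claims_private[i]),
                claims_public_amount=float(claims_public[i] * cost_public[i]),
                claims_private_amount=float(claims_private[i] * cost_private[i]),
            )
        )
    table = StateTable(records, provenance=f"synthetic, seed={config.seed}")
    truth = GroundTruth(
        config=config,
        latent_vulnerability=dict(zip(names, latent.tolist())),
        positions={name: tuple(map(float, positions[i])) for i, name in enumerate(names)},
    )
    return table, truth


def synthetic_boundaries(truth: GroundTruth) -> dict:
    """GeoJSON grid-cell polygons around the generated district points.

    Cells tile [-1, 1]^2, one axis-aligned square per district, so the
    choropleth join over a synthetic state is always complete.
    """
    n = len(truth.positions)
    ncol = math.ceil(math.sqrt(n))
    nrow = math.ceil(n / ncol)
    w, h = 2.0 / ncol, 2.0 / nrow
    features = []
    for name, (cx, cy) in truth.positions.items():
        x0, x1 = cx - w / 2, cx + w / 2
        y0, y1 = cy - h / 2, cy + h / 2
        ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"district": name},
            }
        )
    return {"type": "FeatureCollection", "features": features}


@dataclass
class RecoverySummary:
    """Monte-Carlo summary of full-pipeline sign and magnitude recovery."""

    n_replicates: int
    frac_private_corr_negative: float
    frac_public_corr_positive: float
    mean_lvd_hvd_private_ratio: float
    mean_lvd_hvd_total_ratio: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def recovery_experiment(
    config: GeneratorConfig, n_replicates: int
) -> RecoverySummary:
    """Run the full pipeline on replicate synthetic states.

    Each replicate draws its own stream from a root seed sequence, then
    runs index construction, tertile grouping, pooled rates, LVD:HVD
    ratios and VI correlations; the summary reports how often the
    correlation signs match the generator's effect directions and the
    mean LVD:HVD availability ratios. Ratios with a zero HVD rate are
    excluded from the means.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)

    private_neg = 0
    public_pos = 0
    private_ratios: list[float] = []
    total_ratios: list[float] = []
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        table, _ = generate_state(replace(config, seed=rep_seed))
        scores = build_index(table, DEFAULT_INDICATORS)
        vi = {s.district_name: s.vi for s in scores}

        frame = table.to_frame()
        frame["private_rate"] = frame["hospitals_private"] / frame["enrolled_persons"] * 1e5
        frame["public_rate"] = frame["hospitals_public"] / frame["enrolled_persons"] * 1e5
        results = correlation_table(
            frame, vi=vi, indicators=["private_rate", "public_rate"]
        )
        by_name = {res.indicator_name: res for res in results}
        if by_name["private_rate"].defined and by_name["private_rate"].r < 0:
            private_neg += 1
        if by_name["public_rate"].defined and by_name["public_rate"].r > 0:
            public_pos += 1

        for indicator, sink in (
            ("hospitals_private", private_ratios),
            ("hospitals_total", total_ratios),
        ):
            pooled = tertile_aggregate(table, scores, indicator, include_state_total=False)
            hvd = pooled["HVD"].rate_per_100k
            if hvd > 0:
                sink.append(pooled["LVD"].rate_per_100k / hvd)

    return RecoverySummary(
        n_replicates=n_replicates,
        frac_private_corr_negative=private_neg / n_replicates,
        frac_public_corr_positive=public_pos / n_replicates,
        mean_lvd_hvd_private_ratio=float(np.mean(private_ratios)) if private_ratios else math.nan,
        mean_lvd_hvd_total_ratio=float(np.mean(total_ratios)) if total_ratios else math.nan,
    )
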