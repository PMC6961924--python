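"""Hotspot-mapping size estimation.

A validated hotspot ("spot") record carries the minimum and maximum number of
key-population members reported to frequent the venue on a peak day, plus two
mobility responses from on-site interviews: the fraction of interviewed
members who visit more than one spot on a peak day, and the mean number of
spots those mobile members visit. The crude spot count S1 (midpoint of
min/max) is corrected in two fixed steps:

* mobility deflation, removing double counting of members seen at several
  spots::

      S2 = S1 * (1 - p1) + S1 * p1 / m1

  where ``p1`` is the proportion of members (as encountered at spots, i.e.
  attendance-weighted) visiting more than one spot and ``m1`` the mean number
  of spots the mobile ones visit;

* hidden-population inflation, adding the fraction ``p2`` of members who never
  frequent hotspots (estimated from a survey)::

      S3 = S2 / (1 - p2)

The order is fixed — mobility first, hidden second — and both maps are linear
in S1, so adjusting per spot and summing equals adjusting the sum when the
parameters are uniform.

Spot tables are DataFrames with columns
``spot_id, unit_id, typology, min_count, max_count, multi_spot, spots_visited``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import EstimationError, SchemaError
from .util import check_probability, check_unique, round_half_up

TYPOLOGIES = (
    "street",
    "spa",
    "lodge_hotel",
    "shanti",
    "home",
    "brothel",
    "karaoke_nightclub",
    "beach",
    "park",
    "massage_parlour",
    "public_toilet",
    "other",
)

SPOT_COLUMNS = (
    "spot_id",
    "unit_id",
    "typology",
    "min_count",
    "max_count",
    "multi_spot",
    "spots_visited",
)

LEVELS = ("spot", "unit", "district", "province", "national")

__all__ = [
    "TYPOLOGIES",
    "SPOT_COLUMNS",
    "LEVELS",
    "SizeInterval",
    "AdjustmentParams",
    "validate_spots",
    "midpoint_estimate",
    "aggregate_spots",
    "adjust_mobility",
    "adjust_hidden",
    "estimate_mobility_params",
    "pooled_hidden_fraction",
    "typology_distribution",
    "HotspotMapping",
    "HotspotMappingResults",
]


@dataclass(frozen=True)
class SizeInterval:
    """A (min, mid, max) size estimate at some administrative level."""

    level: str
    key: str
    min: float
    mid: float
    max: float

    def __post_init__(self):
        if self.level not in LEVELS:
            raise SchemaError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if not (self.min <= self.mid <= self.max):
            raise SchemaError(
                f"interval for {self.key!r} not ordered: ({self.min}, {self.mid}, {self.max})"
            )

    def rounded(self) -> tuple[int, int, int]:
        """(min, mid, max) rounded half-up for reporting."""
        return tuple(round_half_up(v) for v in (self.min, self.mid, self.max))

    def scaled(self, factor: float) -> "SizeInterval":
        return SizeInterval(self.level, self.key, self.min * factor, self.mid * factor, self.max * factor)


class AdjustmentParams(BaseModel):
    """Mobility and hidden-population adjustment parameters.

    ``p2`` may be a single national proportion or a mapping from region name
    to proportion, in which case a unit -> region mapping must be supplied to
    the estimator so each spot gets its region's hidden fraction.
    """

    model_config = ConfigDict(frozen=True)

    p1: float
    m1: float
    p2: Union[float, dict[str, float]]

    @field_validator("p1")
    @classmethod
    def _p1_range(cls, v):
        # p1 = 1 (everyone mobile) is well defined; only p2 = 1 blows up
        return check_probability(v, "p1", allow_one=True)

    @field_validator("m1")
    @classmethod
    def _m1_range(cls, v):
        if v < 1:
            raise ValueError(f"m1={v} must be >= 1 (mean spots visited)")
        return float(v)

    @field_validator("p2")
    @classmethod
    def _p2_range(cls, v):
        if isinstance(v, dict):
            for k, x in v.items():
                check_probability(x, f"p2[{k}]", allow_one=False)
            return v
        return check_probability(v, "p2", allow_one=False)

    def p2_for(self, region: Optional[str]) -> float:
        if isinstance(self.p2, dict):
            if region not in self.p2:
                raise EstimationError(f"no hidden fraction configured for region {region!r}")
            return self.p2[region]
        return self.p2


def validate_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a validated (Level-2) spot table."""
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise SchemaError(f"spot table missing column(s): {missing}")
    check_unique(spots["spot_id"], "spot_id (double-count guard)")
    bad = spots.index[~spots["typology"].isin(TYPOLOGIES)]
    if len(bad):
        vals = spots.loc[bad, "typology"].unique().tolist()[:5]
        raise SchemaError(f"unknown typology value(s) {vals}; expected one of {TYPOLOGIES}")
    if (spots["min_count"] < 0).any() or (spots["min_count"] > spots["max_count"]).any():
        rows = spots.index[
            (spots["min_count"] < 0) | (spots["min_count"] > spots["max_count"])
        ]
        raise SchemaError(f"min_count/max_count violated at rows {list(rows[:5])}")
    if ((spots["multi_spot"] < 0) | (spots["multi_spot"] > 1)).any():
        raise SchemaError("multi_spot must lie in [0, 1]")
    if (spots["spots_visited"] < 1).any():
        raise SchemaError("spots_visited must be >= 1")
    if ((spots["multi_spot"] > 0) & (spots["spots_visited"] <= 1)).any():
        raise SchemaError("spots with multi_spot > 0 must report spots_visited > 1")
    return spots


def midpoint_estimate(min_count: float, max_count: float) -> float:
    """Single crude estimate from a (min, max) report: the midpoint.

    Reporting rounds half-up, so (2370, 3251) -> 2810.5, reported 2811.
    """
    if min_count < 0 or min_count > max_count:
        raise EstimationError(f"invalid range ({min_count}, {max_count}): need 0 <= min <= max")
    return (float(min_count) + float(max_count)) / 2.0


def aggregate_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Sum validated spot ranges into per-unit size intervals.

    Unit min is the sum of spot minima, unit max the sum of spot maxima; the
    midpoint of the sums equals the sum of spot midpoints exactly.

    Returns a frame indexed by ``unit_id`` with columns ``min, mid, max``.
    """
    validate_spots(spots)
    g = spots.groupby("unit_id")[["min_count", "max_count"]].sum()
    out = pd.DataFrame(
        {
            "min": g["min_count"].astype(float),
            "mid": (g["min_count"] + g["max_count"]) / 2.0,
            "max": g["max_count"].astype(float),
        }
    )
    return out


def adjust_mobility(s1, p1: float, m1: float):
    """Deflate a crude spot count for multi-spot mobility.

    S2 = S1*(1-p1) + S1*p1/m1. Accepts scalars or arrays; S2 <= S1 always,
    with equality iff p1 == 0 or m1 == 1.
    """
    check_probability(p1, "p1", allow_one=True)
    if m1 < 1:
        raise EstimationError(f"m1={m1} must be >= 1")
    s1 = np.asarray(s1, dtype=float) if np.ndim(s1) else float(s1)
    return s1 * (1.0 - p1) + s1 * p1 / m1


def adjust_hidden(s2, p2: float):
    """Inflate a mobility-adjusted count for the never-at-hotspots fraction.

    S3 = S2 / (1 - p2) >= S2; p2 must be in [0, 1).
    """
    check_probability(p2, "p2", allow_one=False)
    s2 = np.asarray(s2, dtype=float) if np.ndim(s2) else float(s2)
    return s2 / (1.0 - p2)


def estimate_mobility_params(spots: pd.DataFrame, weighted: bool = True) -> tuple[float, float]:
    """Pool per-spot mobility responses into (p1, m1).

    By default p1 is the attendance-weighted mean of the spot-level
    ``multi_spot`` fractions (weights: spot midpoints), which makes it the
    proportion of *encounters* belonging to mobile members — the quantity the
    mobility formula needs, since members are interviewed where they are
    counted. m1 is the corresponding mobile-attendance-weighted mean of
    ``spots_visited``. ``weighted=False`` gives the unweighted spot means.
    """
    validate_spots(spots)
    mids = (spots["min_count"].to_numpy(float) + spots["max_count"].to_numpy(float)) / 2.0
    w = mids if weighted else np.ones_like(mids)
    tot = w.sum()
    if tot <= 0:
        return 0.0, 1.0
    ms = spots["multi_spot"].to_numpy(float)
    p1 = float((w * ms).sum() / tot)
    mobile_w = w * ms
    if mobile_w.sum() <= 0:
        return p1, 1.0
    m1 = float((mobile_w * spots["spots_visited"].to_numpy(float)).sum() / mobile_w.sum())
    return p1, m1


def pooled_hidden_fraction(city_p2: Mapping[str, float], city_n: Mapping[str, int]) -> float:
    """Combine per-survey-city hidden fractions into one national p2,
    weighting each city by its survey sample size."""
    cities = list(city_p2)
    num = sum(check_probability(city_p2[c], f"p2[{c}]", allow_one=False) * city_n[c] for c in cities)
    den = sum(city_n[c] for c in cities)
    if den <= 0:
        raise EstimationError("survey sizes must sum to a positive count")
    return num / den


def typology_distribution(spots: pd.DataFrame) -> pd.Series:
    """Percentage of spots per venue typology (sums to 100 within rounding)."""
    if len(spots) == 0:
        raise EstimationError("cannot compute a typology distribution from an empty spot table")
    validate_spots(spots)
    counts = spots["typology"].value_counts()
    return (100.0 * counts / counts.sum()).sort_values(ascending=False)


class HotspotMapping:
    """Hotspot-mapping size-estimation model.

    Parameters
    ----------
    spots
        Validated Level-2 spot table (see :data:`SPOT_COLUMNS`).
    params
        :class:`AdjustmentParams`; if omitted, p1 and m1 are estimated from
        the spot table's mobility responses and p2 defaults to 0 (no hidden
        adjustment).
    region_of
        Optional mapping unit_id -> region name, required when ``params.p2``
        is region-specific.
    weighted_mobility
        Whether p1/m1 estimation weights spots by attendance (default) or
        treats every spot equally.
    """

    def __init__(
        self,
        spots: pd.DataFrame,
        params: Optional[AdjustmentParams] = None,
        region_of: Optional[Mapping[str, str]] = None,
        weighted_mobility: bool = True,
    ):
        self.spots = validate_spots(spots)
        self.region_of = dict(region_of) if region_of else None
        self.weighted_mobility = weighted_mobility
        if params is None:
            p1, m1 = estimate_mobility_params(spots, weighted=weighted_mobility)
            params = AdjustmentParams(p1=p1, m1=m1, p2=0.0)
        self.params = params

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HotspotMapping":
        from .io import read_spots

        return cls(read_spots(path), **kwargs)

    def _p2_of_unit(self, unit_id) -> float:
        if isinstance(self.params.p2, dict):
            if self.region_of is None:
                raise EstimationError(
                    "region-specific p2 supplied but no unit->region mapping given"
                )
            return self.params.p2_for(self.region_of.get(unit_id))
        return float(self.params.p2)

    def fit(self) -> "HotspotMappingResults":
        """Aggregate spots per unit and apply the S1 -> S2 -> S3 chain.

        Adjustments are applied per spot and then summed; with uniform
        parameters this equals adjusting the unit sums directly.
        """
        crude = aggregate_spots(self.spots)
        p1, m1 = self.params.p1, self.params.m1
        s2 = crude.apply(lambda col: adjust_mobility(col.to_numpy(), p1, m1))
        p2 = np.array([self._p2_of_unit(u) for u in crude.index], dtype=float)
        s3 = s2.div(1.0 - p2, axis=0)
        return HotspotMappingResults(
            model=self, crude=crude, mobility_adjusted=s2, fully_adjusted=s3
        )


@dataclass
class HotspotMappingResults:
    """Per-unit crude, mobility-adjusted and hidden-adjusted size intervals.

    Each table is indexed by ``unit_id`` with columns ``min, mid, max``.
    """

    model: HotspotMapping
    crude: pd.DataFrame
    mobility_adjusted: pd.DataFrame
    fully_adjusted: pd.DataFrame
    typology: pd.Series = field(init=False)

    def __post_init__(self):
        self.typology = typology_distribution(self.model.spots)

    def national(self, stage: str = "fully_adjusted") -> SizeInterval:
        """Sum the per-unit intervals of one adjustment stage nationally."""
        table = getattr(self, stage)
        return SizeInterval(
            "national", "all", table["min"].sum(), table["mid"].sum(), table["max"].sum()
        )

    def unit_intervals(self, stage: str = "fully_adjusted") -> list[SizeInterval]:
        table = getattr(self, stage)
        return [
            SizeInterval("unit", str(u), r["min"], r["mid"], r["max"])
            for u, r in table.iterrows()
        ]

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Hotspot mapping size estimate",
            "=" * 45,
            f"Spots: {len(self.model.spots)}   Units: {len(self.crude)}",
            f"p1 (multi-spot proportion): {p.p1:.4f}",
            f"m1 (mean spots visited):    {p.m1:.4f}",
            f"p2 (hidden fraction):       {p.p2 if isinstance(p.p2, dict) else format(p.p2, '.4f')}",
            "",
            f"{'stage':<22}{'min':>10}{'mid':>10}{'max':>10}",
        ]
        for stage, label in [
            ("crude", "crude (S1)"),
            ("mobility_adjusted", "mobility-adj (S2)"),
            ("fully_adjusted", "hidden-adj (S3)"),
        ]:
            lo, mid, hi = self.national(stage).rounded()
            lines.append(f"{label:<22}{lo:>10}{mid:>10}{hi:>10}")
        lines.append("")
        lines.append("Spot typology (%):")
        for name, pct in self.typology.items():
            lines.append(f"  {name:<20}{pct:>6.1f}")
        return "\n".join(lines)
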