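"""Synthetic country with a known hidden key population.

Every downstream stage (mapping, extrapolation, multiplier, survey
estimation) can be tested against ground truth by generating a country whose
key-population sizes are known by construction:

* administrative units with log-uniform census populations spanning three
  density strata, grouped into districts and provinces;
* key-population members assigned binomially to units, each carrying a hidden
  flag (never attends venues, probability ``hidden_prob``), a mobility flag
  (visits several venues on a peak day, probability ``mobility_prob`` with
  ``spots_visited_mean`` venues), a heavy-tailed personal network size, and
  Bernoulli service-contact / unique-object flags with known coverage;
* venues ("spots") per unit with Poisson intensity, attended by the visible
  members of the unit;
* mapping observations: per-spot min/max counts bracketing true peak-day
  attendance under a symmetric reporting-noise fraction, plus the mobility
  responses an interviewer would pool from attendees;
* service registries (de-duplicated counts per source) and a degree-biased
  survey sample with a recruitment forest, emulating RDS.

All randomness flows from one generator seeded by ``SimConfig.seed``, so an
identical config reproduces every table bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ConfigurationError
from .frame import CENSUS_COLUMNS, stratify_units
from .mapping import TYPOLOGIES
from .util import round_half_up

# venue-type frequencies used to label synthetic spots; chosen to resemble
# the mix reported for street-based sex-work settings in South Asia
DEFAULT_TYPOLOGY_WEIGHTS = {
    "street": 0.395,
    "spa": 0.208,
    "lodge_hotel": 0.138,
    "shanti": 0.096,
    "home": 0.092,
    "other": 0.019,
    "brothel": 0.018,
    "karaoke_nightclub": 0.011,
    "beach": 0.009,
    "park": 0.009,
    "massage_parlour": 0.004,
}

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticData",
    "generate_country",
    "generate_mapping_observations",
    "generate_service_data",
    "simulate_all",
]


class SimConfig(BaseModel):
    """Generative parameters of the synthetic country.

    Defaults emulate the island-wide study conditions this package targets:
    331 units spanning census populations from a few hundred to ~320k, a key
    population of roughly half a percent of adult females, a fifth of
    spot-goers mobile across two venues on a peak day, and a majority-hidden
    population (the survey cities reported 48-74% never visiting outdoor
    venues).
    """

    model_config = ConfigDict(frozen=True)

    n_units: int = 331
    pop_range: tuple[int, int] = (298, 323_257)
    adult_fraction: float = 0.52  # share of total population aged 15-49
    female_share: float = 0.505
    kp_prevalence: Union[float, dict[str, float]] = 0.0056
    kp_base: str = "adult_f"  # census column the prevalence applies to
    hidden_prob: float = 0.58  # p2
    mobility_prob: float = 0.206  # p1
    spots_visited_mean: float = 2.0  # m1, >= 2 whenever mobility_prob > 0
    spots_per_unit_rate: float = 4.0  # units get 1 + Poisson(rate) venues
    service_coverage: dict[str, float] = {"ngo_clients": 0.25, "condoms": 0.30}
    object_coverage: float = 0.05
    survey_size: int = 450
    n_seeds: int = 8
    max_recruits: int = 3
    degree_mean: float = 10.0
    degree_shape: float = 2.0  # negative-binomial dispersion of degree - 1
    dependence_or: float = 1.0  # odds ratio service-contact <-> survey inclusion
    seed: int = 0

    @field_validator("n_units")
    @classmethod
    def _units(cls, v):
        if v < 3:
            raise ValueError("n_units must be >= 3 (three density strata)")
        return v

    @field_validator("hidden_prob", "mobility_prob", "object_coverage")
    @classmethod
    def _probs(cls, v, info):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name}={v} must lie in [0, 1]")
        return v

    @field_validator("kp_prevalence")
    @classmethod
    def _prev(cls, v):
        vals = v.values() if isinstance(v, dict) else [v]
        for x in vals:
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"kp_prevalence value {x} must lie in [0, 1]")
        return v

    @field_validator("service_coverage")
    @classmethod
    def _cov(cls, v):
        for name, x in v.items():
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"service_coverage[{name}]={x} must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if self.pop_range[0] < 1 or self.pop_range[0] > self.pop_range[1]:
            raise ValueError(f"pop_range {self.pop_range} must satisfy 1 <= lo <= hi")
        if self.spots_visited_mean < 1:
            raise ValueError("spots_visited_mean must be >= 1")
        if self.mobility_prob > 0 and self.spots_visited_mean < 2:
            raise ValueError("mobile individuals must average >= 2 spots")
        if self.dependence_or <= 0:
            raise ValueError("dependence_or must be positive")
        return self

    def prevalence_for(self, stratum: str) -> float:
        if isinstance(self.kp_prevalence, dict):
            if stratum not in self.kp_prevalence:
                raise ConfigurationError(f"no kp_prevalence for stratum {stratum!r}")
            return self.kp_prevalence[stratum]
        return self.kp_prevalence


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated country.

    ``units`` extends the census table with the true per-unit KP count;
    ``individuals`` carries one row per KP member with all latent attributes;
    ``attendance`` lists (individual_id, spot_id) visit pairs on the peak day.
    Hidden individuals attend zero spots, and the per-unit counts always sum
    to the national truth.
    """

    config: SimConfig
    units: pd.DataFrame
    individuals: pd.DataFrame
    spots: pd.DataFrame
    attendance: pd.DataFrame

    @property
    def census(self) -> pd.DataFrame:
        return self.units[list(CENSUS_COLUMNS)].copy()

    @property
    def national_truth(self) -> int:
        return int(len(self.individuals))

    @property
    def unit_truth(self) -> pd.Series:
        return self.units.set_index("unit_id")["kp_count"]

    def true_adjustment_params(self):
        """Generative adjustment parameters on the scale the formulas expect.

        The mobility formula wants the proportion of *encounters* (spot
        attendances) contributed by mobile members, because interviews at
        venues sample attendance events; a mobile member visiting ``m1``
        venues is encountered ``m1`` times. For generative individual-level
        probability ``p1`` that converts to ``p1*m1 / (1 - p1 + p1*m1)``.
        """
        from .mapping import AdjustmentParams

        p1, m1 = self.config.mobility_prob, self.config.spots_visited_mean
        p1_enc = p1 * m1 / (1.0 - p1 + p1 * m1)
        return AdjustmentParams(p1=p1_enc, m1=m1, p2=self.config.hidden_prob)

    def truth_dict(self) -> dict:
        """JSON-ready truth sidecar for test harnesses."""
        ind = self.individuals
        return {
            "national_truth": self.national_truth,
            "visible_truth": int((~ind["hidden"]).sum()),
            "unit_truth": {str(k): int(v) for k, v in self.unit_truth.items()},
            "hidden_prob": self.config.hidden_prob,
            "mobility_prob": self.config.mobility_prob,
            "spots_visited_mean": self.config.spots_visited_mean,
            "service_truth": {
                src: int(ind[f"received_{src}"].sum())
                for src in self.config.service_coverage
            },
            "object_truth": int(ind["received_unique_object"].sum()),
        }


def generate_country(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[SyntheticTruth, pd.DataFrame]:
    """Generate the census table and the individual-level ground truth.

    Unit populations are log-uniform over ``pop_range`` (administrative units
    are strongly right-skewed); per-unit KP counts are Binomial(base adults,
    prevalence), with the prevalence optionally stratum-specific.

    Returns ``(truth, census)``; ``census`` is the plain census view of
    ``truth.units``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_units
    lo, hi = config.pop_range
    pops = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    pops = np.maximum(1, round_half_up(pops))
    width = max(len(str(n)), 3)
    units = pd.DataFrame(
        {
            "unit_id": [f"DS{i:0{width}d}" for i in range(1, n + 1)],
            "total_pop": pops,
        }
    )
    adults = units["total_pop"] * config.adult_fraction
    units["adult_f"] = round_half_up(adults * config.female_share)
    units["adult_m"] = round_half_up(adults * (1 - config.female_share))
    # contiguous district/province blocks over the unit index
    n_district = min(25, max(1, n // 4))
    n_province = min(9, n_district)
    idx = np.arange(n)
    units["district"] = [f"D{1 + i * n_district // n:02d}" for i in idx]
    units["province"] = [f"P{1 + i * n_province // n}" for i in idx]

    strata = stratify_units(units).set_index("unit_id")["stratum"]
    prev = np.array([config.prevalence_for(strata[u]) for u in units["unit_id"]])
    base = units[config.kp_base].to_numpy()
    units["kp_count"] = rng.binomial(base, prev)

    individuals = pd.DataFrame(
        {
            "individual_id": np.arange(int(units["kp_count"].sum())),
            "unit_id": np.repeat(units["unit_id"].to_numpy(), units["kp_count"].to_numpy()),
        }
    )
    m = len(individuals)
    individuals["hidden"] = rng.random(m) < config.hidden_prob
    visible = ~individuals["hidden"].to_numpy()
    individuals["mobile"] = np.where(visible, rng.random(m) < config.mobility_prob, False)

    # intended number of distinct spots: 1 for sedentary spot-goers, around
    # spots_visited_mean (randomised between its floor and ceiling) for mobile
    m1 = config.spots_visited_mean
    m1_lo, frac = int(np.floor(m1)), m1 - np.floor(m1)
    intended = np.where(
        individuals["mobile"], m1_lo + (rng.random(m) < frac).astype(int), 1
    )
    intended = np.where(visible, intended, 0)

    shape = config.degree_shape
    mean_extra = max(config.degree_mean - 1.0, 1e-9)
    individuals["degree"] = 1 + rng.negative_binomial(
        shape, shape / (shape + mean_extra), size=m
    )
    for src, cov in config.service_coverage.items():
        individuals[f"received_{src}"] = (rng.random(m) < cov).astype(int)
    individuals["received_unique_object"] = (rng.random(m) < config.object_coverage).astype(int)

    # venues per unit: at least one wherever anyone could attend
    n_spots_u = 1 + rng.poisson(config.spots_per_unit_rate, size=n)
    typ_names = list(DEFAULT_TYPOLOGY_WEIGHTS)
    typ_p = np.array(list(DEFAULT_TYPOLOGY_WEIGHTS.values()))
    typ_p = typ_p / typ_p.sum()
    spots = pd.DataFrame(
        {
            "spot_id": [
                f"{u}-S{j}" for u, k in zip(units["unit_id"], n_spots_u) for j in range(1, k + 1)
            ],
            "unit_id": np.repeat(units["unit_id"].to_numpy(), n_spots_u),
        }
    )
    spots["typology"] = rng.choice(typ_names, size=len(spots), p=typ_p)
    assert set(spots["typology"]) <= set(TYPOLOGIES)

    # attendance: visible members pick distinct venues within the home unit
    spot_ids_of = {u: g["spot_id"].to_numpy() for u, g in spots.groupby("unit_id")}
    att_ind: list[np.ndarray] = []
    att_spot: list[np.ndarray] = []
    ind_unit = individuals["unit_id"].to_numpy()
    ind_id = individuals["individual_id"].to_numpy()
    for u in units["unit_id"]:
        sel = np.flatnonzero(ind_unit == u)
        if len(sel) == 0:
            continue
        unit_spots = spot_ids_of[u]
        k_int = np.minimum(intended[sel], len(unit_spots))
        singles = sel[k_int == 1]
        if len(singles):
            att_ind.append(ind_id[singles])
            att_spot.append(unit_spots[rng.integers(0, len(unit_spots), len(singles))])
        for i in sel[k_int > 1]:
            k = int(min(intended[i], len(unit_spots)))
            att_ind.append(np.full(k, ind_id[i]))
            att_spot.append(rng.choice(unit_spots, size=k, replace=False))
    attendance = pd.DataFrame(
        {
            "individual_id": np.concatenate(att_ind) if att_ind else np.array([], dtype=int),
            "spot_id": np.concatenate(att_spot) if att_spot else np.array([], dtype=object),
        }
    )
    n_attended = attendance.groupby("individual_id").size()
    individuals["spots_attended"] = (
        individuals["individual_id"].map(n_attended).fillna(0).astype(int)
    )

    truth = SyntheticTruth(
        config=config,
        units=units,
        individuals=individuals,
        spots=spots,
        attendance=attendance,
    )
    return truth, truth.census


def generate_mapping_observations(
    truth: SyntheticTruth,
    noise: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Turn true peak-day attendance into a Level-2 validated spot table.

    Informants report a (min, max) bracket around the true attendance: each
    bound is perturbed by an independent Uniform(0, noise) relative error,
    downward for the minimum and upward for the maximum, so the bracket
    always contains the truth and the midpoint is unbiased up to rounding.
    Mobility responses pool the spot's actual attendees: the fraction who
    visited more than one venue and the mean venues visited among those.
    Spots nobody attends are never validated and are dropped.
    """
    if not 0.0 <= noise < 1.0:
        raise ConfigurationError(f"noise={noise} must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 1)
    att = truth.attendance.merge(
        truth.individuals[["individual_id", "spots_attended"]], on="individual_id"
    )
    if len(att) == 0:
        return pd.DataFrame(
            columns=[
                "spot_id",
                "unit_id",
                "typology",
                "min_count",
                "max_count",
                "multi_spot",
                "spots_visited",
            ]
        )
    g = att.groupby("spot_id")
    per_spot = pd.DataFrame(
        {
            "attendance": g.size(),
            "n_mobile": g["spots_attended"].apply(lambda s: int((s > 1).sum())),
            "mean_mobile_spots": g["spots_attended"].apply(
                lambda s: float(s[s > 1].mean()) if (s > 1).any() else 1.0
            ),
        }
    )
    k = len(per_spot)
    a = per_spot["attendance"].to_numpy(dtype=float)
    eps_lo = rng.uniform(0.0, noise, size=k) if noise else np.zeros(k)
    eps_hi = rng.uniform(0.0, noise, size=k) if noise else np.zeros(k)
    obs = per_spot.reset_index().merge(truth.spots, on="spot_id")
    obs["min_count"] = round_half_up(a * (1.0 - eps_lo))
    obs["max_count"] = np.maximum(round_half_up(a * (1.0 + eps_hi)), obs["min_count"])
    obs["multi_spot"] = per_spot["n_mobile"].to_numpy() / a
    obs["spots_visited"] = np.where(
        obs["multi_spot"] > 0, obs["mean_mobile_spots"], 1.0
    )
    return obs[
        [
            "spot_id",
            "unit_id",
            "typology",
            "min_count",
            "max_count",
            "multi_spot",
            "spots_visited",
        ]
    ].sort_values("spot_id", ignore_index=True)


def generate_service_data(
    truth: SyntheticTruth, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce the NGO registry counts and the RDS-style survey table.

    Registry counts are exact de-duplicated tallies of the service flags, so
    each count is Binomial(N_true, coverage) by construction; the unique
    object count appears as source ``unique_object``. The survey draws
    ``survey_size`` members without replacement with probability proportional
    to network degree (times ``dependence_or`` for members known to any
    service, when that knob is on), then assigns a recruitment forest with
    ``n_seeds`` seeds and at most ``max_recruits`` recruits per respondent.
    """
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    ind = truth.individuals
    sources = list(cfg.service_coverage) + ["unique_object"]
    registry = pd.DataFrame(
        {
            "source_name": sources,
            "count": [int(ind[f"received_{s}"].sum()) for s in sources],
        }
    )

    n = cfg.survey_size
    if n > len(ind):
        raise ConfigurationError(
            f"survey_size={n} exceeds the key population ({len(ind)} members)"
        )
    w = ind["degree"].to_numpy(dtype=float).copy()
    if cfg.dependence_or != 1.0:
        in_any = np.zeros(len(ind), dtype=bool)
        for s in sources:
            in_any |= ind[f"received_{s}"].to_numpy(dtype=bool)
        w = w * np.where(in_any, cfg.dependence_or, 1.0)
    # weighted draw without replacement (Efraimidis-Spirakis keys); the key
    # order doubles as the recruitment order
    keys = rng.random(len(ind)) ** (1.0 / w)
    order = np.argsort(-keys)[:n]

    recruiter = np.full(n, "", dtype=object)
    capacity: list[int] = []
    open_slots: list[int] = []
    resp_ids = ind["individual_id"].to_numpy()[order].astype(str)
    n_seeds = min(cfg.n_seeds, n)
    for i in range(n):
        if i >= n_seeds:
            j = open_slots[rng.integers(0, len(open_slots))]
            recruiter[i] = resp_ids[j]
            capacity[j] -= 1
            if capacity[j] == 0:
                open_slots.remove(j)
        capacity.append(cfg.max_recruits)
        open_slots.append(i)
    survey = pd.DataFrame(
        {
            "respondent_id": resp_ids,
            "recruiter_id": recruiter,
            "degree": ind["degree"].to_numpy()[order],
        }
    )
    for s in sources:
        survey[f"received_{s}"] = ind[f"received_{s}"].to_numpy()[order]
    survey["hidden"] = ind["hidden"].to_numpy()[order].astype(int)
    return registry, survey


@dataclass
class SyntheticData:
    """One complete simulated study: truth plus every observable table."""

    truth: SyntheticTruth
    census: pd.DataFrame
    spots: pd.DataFrame
    registry: pd.DataFrame
    survey: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables as CSV plus a JSON truth sidecar; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("census", self.census),
            ("spots", self.spots),
            ("registry", self.registry),
            ("survey", self.survey),
        ]:
            paths[name] = outdir / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(
            json.dumps(self.truth.truth_dict(), indent=2, sort_keys=True)
        )
        return paths


def simulate_all(config: SimConfig, noise: float = 0.0) -> SyntheticData:
    """Run the whole generator off one seeded stream: country, mapping
    observations, registries and survey."""
    rng = np.random.default_rng(config.seed)
    truth, census = generate_country(config, rng)
    spots = generate_mapping_observations(truth, noise=noise, rng=rng)
    registry, survey = generate_service_data(truth, rng)
    return SyntheticData(
        truth=truth, census=census, spots=spots, registry=registry, survey=survey
    )
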