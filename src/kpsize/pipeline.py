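"""End-to-end orchestration: one config in, one auditable report bundle out.

A run reads the input tables named in a :class:`RunConfig`, executes the
stages that have inputs (mapping -> extrapolation always; multiplier and
Delphi when their tables are present), and writes every intermediate and
final product to the output directory:

* ``unit_estimates.csv`` — per-unit crude / mobility-adjusted / fully
  adjusted intervals;
* ``estimates.csv`` — tidy extrapolated intervals at unit, district,
  province and national level;
* ``diagnostics.json`` — pooled proportions, linearity R², parameters used;
* ``multiplier.json`` / ``consensus.json`` — stage reports when run;
* ``run.log`` — every parameter value and named operation, with no
  wall-clock content, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io as kio
from .errors import ConfigurationError
from .extrapolate import Extrapolation
from .delphi import DelphiPanel
from .mapping import AdjustmentParams, HotspotMapping, estimate_mobility_params
from .multiplier import ServiceMultiplier, rds_proportion

__all__ = ["RunConfig", "run_pipeline"]


class RunConfig(BaseModel):
    """Paths, parameters and seeds for one reproducible pipeline run."""

    model_config = ConfigDict(frozen=True)

    census_path: str
    spots_path: str
    registry_path: Optional[str] = None
    survey_path: Optional[str] = None
    ballots_path: Optional[str] = None
    params_path: Optional[str] = None  # YAML p1/m1/p2; omitted -> estimated
    sampled_units: Optional[list[str]] = None  # default: units in the spot table
    region_of: Optional[dict[str, str]] = None  # unit -> region, for regional p2
    indicator_map: Optional[dict[str, str]] = None
    hidden_indicator: str = "hidden"
    n_boot: int = 500
    seed: int = 0
    outdir: str = "kpsize_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for field in ("census_path", "spots_path"):
            if not Path(getattr(cfg, field)).exists():
                raise ConfigurationError(f"{field} does not exist: {getattr(cfg, field)}")
        return cfg


def _resolve_params(cfg: RunConfig, spots: pd.DataFrame, survey) -> AdjustmentParams:
    if cfg.params_path:
        return kio.read_adjustment_params(cfg.params_path)
    p1, m1 = estimate_mobility_params(spots)
    p2 = 0.0
    if survey is not None and cfg.hidden_indicator in survey.columns:
        p2 = rds_proportion(
            survey, cfg.hidden_indicator, n_boot=cfg.n_boot, seed=cfg.seed
        ).p_hat
    return AdjustmentParams(p1=p1, m1=m1, p2=p2)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage; returns the report bundle as a dict and
    writes it under ``cfg.outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {cfg.model_dump_json(exclude_none=True)}"]

    census = kio.read_census(cfg.census_path)
    spots = kio.read_spots(cfg.spots_path)
    log.append(f"read_census: {len(census)} units from {cfg.census_path}")
    log.append(f"read_spots: {len(spots)} validated spots from {cfg.spots_path}")

    survey = None
    if cfg.survey_path:
        indicators = list((cfg.indicator_map or {}).values())
        survey = kio.read_survey(cfg.survey_path, indicators=indicators)
        log.append(f"read_survey: {len(survey)} respondents from {cfg.survey_path}")

    params = _resolve_params(cfg, spots, survey)
    log.append(
        f"adjustment_params: p1={params.p1:.6f} m1={params.m1:.6f} p2={params.p2}"
        + (" (from file)" if cfg.params_path else " (estimated from data)")
    )

    mapping = HotspotMapping(spots, params=params, region_of=cfg.region_of).fit()
    unit_csv = out / "unit_estimates.csv"
    stacked = pd.concat(
        {
            "crude": mapping.crude,
            "mobility_adjusted": mapping.mobility_adjusted,
            "fully_adjusted": mapping.fully_adjusted,
        },
        names=["stage", "unit_id"],
    )
    stacked.to_csv(unit_csv)
    log.append(f"aggregate_spots+adjust: wrote {unit_csv}")

    sampled = cfg.sampled_units or sorted(spots["unit_id"].unique())
    unknown = set(sampled) - set(census["unit_id"])
    if unknown:
        raise ConfigurationError(f"sampled units not in census: {sorted(unknown)[:5]}")
    unit_est = mapping.fully_adjusted.reindex(sampled, fill_value=0.0)
    extra = Extrapolation(unit_est, census).fit()
    est_csv = out / "estimates.csv"
    extra.tidy().to_csv(est_csv, index=False)
    log.append(
        f"extrapolate: pooled p_mid={extra.pooled.p_mid:.8f} over {len(sampled)} "
        f"sampled units, R^2={extra.r_squared:.4f}, wrote {est_csv}"
    )

    bundle: dict = {
        "mapping_national": dict(
            zip(("min", "mid", "max"), mapping.national("fully_adjusted").rounded())
        ),
        "extrapolated_national": dict(zip(("min", "mid", "max"), extra.national.rounded())),
        "diagnostics": {
            "pooled_proportion": {
                "min": extra.pooled.p_low,
                "mid": extra.pooled.p_mid,
                "max": extra.pooled.p_high,
            },
            "r_squared": extra.r_squared,
            "params": {"p1": params.p1, "m1": params.m1, "p2": params.p2},
            "n_sampled_units": len(sampled),
        },
    }
    kio.write_json(bundle["diagnostics"], out / "diagnostics.json")

    if cfg.registry_path and cfg.survey_path:
        registry = kio.read_registry(cfg.registry_path)
        mult = ServiceMultiplier(
            survey,
            registry,
            indicator_map=cfg.indicator_map,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
        ).fit()
        bundle["multiplier"] = mult.to_dict()
        kio.write_json(bundle["multiplier"], out / "multiplier.json")
        log.append(f"multiplier: {len(mult.estimates)} sources, median N={mult.synthesis.n_hat:.1f}")

    if cfg.ballots_path:
        panel = DelphiPanel(kio.read_ballots(cfg.ballots_path)).fit()
        bundle["consensus"] = panel.to_dict()
        kio.write_json(bundle["consensus"], out / "consensus.json")
        log.append(f"delphi: consensus point={panel.consensus.point:.0f}")

    (out / "run.log").write_text("\n".join(log) + "\n")
    return bundle
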