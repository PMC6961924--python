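"""Service / unique-object multiplier size estimation from RDS surveys.

The multiplier method crosses two data sources that overlap in a known way:
a de-duplicated count ``n`` of key-population members who received a service
(or a unique object) in a reference period, and the survey-estimated
proportion ``p`` of the population reporting that contact. The population
size is then

    N = n / p,

with the 95% interval obtained by inverting the proportion's interval:
``N_low = n / p_high`` and ``N_high = n / p_low``. Several single-source
estimates for a city are synthesised by their component-wise median, which
resists any one source's bias.

Survey proportions come from a respondent-driven sample (RDS), a chain
referral design in which high-degree members are over-recruited. The
proportion is design-adjusted with the RDS-II (Volz–Heckathorn) estimator,

    p_hat = sum(y_i / d_i) / sum(1 / d_i),

where ``d_i`` is respondent i's personal network size, and its confidence
interval comes from a seeded recruitment-chain bootstrap in the style of
Salganik: synthetic chains are regrown by resampling respondents conditional
on the indicator value of their recruiter, preserving the referral dependence
structure, and the 2.5/97.5 percentiles of the replicate estimates are taken.

Survey tables are DataFrames with columns ``respondent_id, recruiter_id``
(empty for seeds), ``degree`` and one 0/1 column per indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, SchemaError, UndefinedEstimateError

SURVEY_COLUMNS = ("respondent_id", "recruiter_id", "degree")

__all__ = [
    "SURVEY_COLUMNS",
    "ProportionEstimate",
    "MultiplierInput",
    "MultiplierEstimate",
    "validate_survey",
    "rds_proportion",
    "multiplier_estimate",
    "synthesize_median",
    "ServiceMultiplier",
    "ServiceMultiplierResults",
]


@dataclass(frozen=True)
class ProportionEstimate:
    """A design-adjusted survey proportion with a 95% interval."""

    p_hat: float
    ci_low: float
    ci_high: float
    n_eff: int

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0):
            raise EstimationError(
                f"proportion interval not ordered in [0,1]: "
                f"({self.ci_low}, {self.p_hat}, {self.ci_high})"
            )

    @property
    def degenerate(self) -> bool:
        """True when the estimate sits on the boundary (all or no positives)."""
        return self.p_hat in (0.0, 1.0) or self.ci_low == self.ci_high


@dataclass(frozen=True)
class MultiplierInput:
    """A service count paired with the matching survey proportion.

    The count and the indicator must refer to the same reference period;
    record it in ``period`` so mismatches are auditable.
    """

    source_name: str
    count: float
    proportion: ProportionEstimate
    period: str = ""

    def __post_init__(self):
        if self.count < 0:
            raise SchemaError(f"{self.source_name}: count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class MultiplierEstimate:
    """A population size estimate N = n/p with its inverted 95% interval."""

    source_name: str
    n_hat: float
    ci_low: float
    ci_high: float
    degenerate: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.n_hat <= self.ci_high):
            raise EstimationError(
                f"{self.source_name}: size interval not ordered "
                f"({self.ci_low}, {self.n_hat}, {self.ci_high})"
            )


def validate_survey(survey: pd.DataFrame, indicators: Sequence[str] = ()) -> pd.DataFrame:
    """Schema and forest checks for an RDS survey table.

    Degrees must be >= 1; every non-empty recruiter must itself be a
    respondent; recruitment must be a forest (no cycles).
    """
    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise SchemaError(f"survey table missing column(s): {missing}")
    for ind in indicators:
        if ind not in survey.columns:
            raise SchemaError(f"survey table has no indicator column {ind!r}")
        vals = survey[ind]
        if vals.isna().any() or ~vals.isin([0, 1]).all():
            raise SchemaError(f"indicator {ind!r} must be 0/1 for every respondent")
    if (survey["degree"] < 1).any():
        rows = survey.index[survey["degree"] < 1]
        raise SchemaError(f"degree must be >= 1 (rows {list(rows[:5])})")
    ids = set(survey["respondent_id"])
    if len(ids) != len(survey):
        raise SchemaError("respondent_id values must be unique")
    parent = dict(zip(survey["respondent_id"], survey["recruiter_id"]))

    def is_seed(r):
        return pd.isna(r) or r == ""

    for rid, rec in parent.items():
        if not is_seed(rec) and rec not in ids:
            raise SchemaError(f"respondent {rid!r} names unknown recruiter {rec!r}")
    # cycle check by walking parent pointers with memoised roots
    state: dict = {}
    for rid in parent:
        path = []
        cur = rid
        while state.get(cur) is None and not is_seed(parent[cur]):
            if cur in path:
                raise SchemaError(f"recruitment cycle involving respondent {cur!r}")
            path.append(cur)
            cur = parent[cur]
        for p in path:
            state[p] = True
        state[cur] = True
    return survey


def _rds2(y: np.ndarray, d: np.ndarray) -> float:
    return float((y / d).sum() / (1.0 / d).sum())


def rds_proportion(
    survey: pd.DataFrame,
    indicator: str,
    n_boot: int = 500,
    seed: Optional[int] = None,
) -> ProportionEstimate:
    """RDS-II proportion of a 0/1 survey indicator with a bootstrap 95% CI.

    The point estimate weights each respondent by the inverse of their
    personal network size. The interval regrows ``n_boot`` synthetic
    recruitment chains of the observed sample size: a chain starts from a
    random seed respondent and each subsequent draw is resampled (with
    replacement) from the respondents whose recruiter carried the current
    indicator value, reproducing the referral dependence between adjacent
    recruits; percentile bounds are reported. Fully reproducible for a fixed
    ``seed``.
    """
    validate_survey(survey, indicators=[indicator])
    y = survey[indicator].to_numpy(dtype=float)
    d = survey["degree"].to_numpy(dtype=float)
    n = len(survey)
    if n == 0:
        raise EstimationError("empty survey")
    p_hat = _rds2(y, d)

    rng = np.random.default_rng(seed)
    rec = survey["recruiter_id"]
    is_seed = rec.isna() | (rec.astype(object) == "")
    seed_idx = np.flatnonzero(is_seed.to_numpy())
    if len(seed_idx) == 0:  # degenerate forest: treat everyone as a seed
        seed_idx = np.arange(n)
    rec_y = survey.set_index("respondent_id")[indicator]
    recruiter_val = np.full(n, -1, dtype=int)  # -1 marks seeds
    not_seed = ~is_seed.to_numpy()
    recruiter_val[not_seed] = rec_y.loc[rec[not_seed]].to_numpy(dtype=int)
    pools = {v: np.flatnonzero(recruiter_val == v) for v in (0, 1)}
    everyone = np.arange(n)
    pools = {v: (idx if len(idx) else everyone) for v, idx in pools.items()}

    cur = rng.choice(seed_idx, size=n_boot)
    num = y[cur] / d[cur]
    den = 1.0 / d[cur]
    states = y[cur].astype(int)
    for _ in range(n - 1):
        nxt = np.empty(n_boot, dtype=int)
        for v in (0, 1):
            mask = states == v
            k = int(mask.sum())
            if k:
                pool = pools[v]
                nxt[mask] = pool[rng.integers(0, len(pool), size=k)]
        cur = nxt
        num += y[cur] / d[cur]
        den += 1.0 / d[cur]
        states = y[cur].astype(int)
    p_boot = num / den
    lo, hi = np.percentile(p_boot, [2.5, 97.5])
    # percentile bounds need not bracket the weighted point estimate in
    # pathological samples; clip so the interval always contains p_hat
    lo, hi = min(float(lo), p_hat), max(float(hi), p_hat)
    return ProportionEstimate(p_hat=p_hat, ci_low=lo, ci_high=hi, n_eff=n)


def multiplier_estimate(inp: MultiplierInput) -> MultiplierEstimate:
    """Single-source multiplier size estimate: N = n / p with CI inversion.

    The size interval inverts the proportion interval end-for-end:
    a *larger* coverage proportion implies a *smaller* population, so
    N_low = n / p_high and N_high = n / p_low.
    """
    p = inp.proportion
    if p.p_hat <= 0 or p.ci_low <= 0:
        raise UndefinedEstimateError(
            f"{inp.source_name}: survey proportion (or its lower bound) is zero; "
            f"N = n/p is undefined"
        )
    return MultiplierEstimate(
        source_name=inp.source_name,
        n_hat=inp.count / p.p_hat,
        ci_low=inp.count / p.ci_high,
        ci_high=inp.count / p.ci_low,
        degenerate=p.degenerate,
    )


def synthesize_median(estimates: Sequence[MultiplierEstimate]) -> MultiplierEstimate:
    """Median synthesis of several multiplier estimates.

    Component-wise median of the point estimates and of each bound; an even
    number of estimates uses the mean of the central pair.
    """
    if len(estimates) == 0:
        raise EstimationError("cannot synthesise an empty list of estimates")
    return MultiplierEstimate(
        source_name="median",
        n_hat=float(median(e.n_hat for e in estimates)),
        ci_low=float(median(e.ci_low for e in estimates)),
        ci_high=float(median(e.ci_high for e in estimates)),
        degenerate=any(e.degenerate for e in estimates),
    )


class ServiceMultiplier:
    """Multiplier size-estimation model for one survey city.

    Parameters
    ----------
    survey
        RDS survey table (``respondent_id, recruiter_id, degree`` plus one
        0/1 column per indicator).
    registry
        Mapping ``source_name -> de-duplicated count`` or a DataFrame with
        columns ``source_name, count`` (see :func:`kpsize.io.read_registry`).
    indicator_map
        ``source_name -> survey indicator column``. Defaults to
        ``received_<source_name>``.
    """

    def __init__(
        self,
        survey: pd.DataFrame,
        registry: Mapping[str, float] | pd.DataFrame,
        indicator_map: Optional[Mapping[str, str]] = None,
        n_boot: int = 500,
        seed: Optional[int] = None,
    ):
        if isinstance(registry, pd.DataFrame):
            missing = [c for c in ("source_name", "count") if c not in registry.columns]
            if missing:
                raise SchemaError(f"registry table missing column(s): {missing}")
            registry = dict(zip(registry["source_name"], registry["count"]))
        self.registry = dict(registry)
        self.indicator_map = {
            src: (indicator_map or {}).get(src, f"received_{src}") for src in self.registry
        }
        self.survey = validate_survey(survey, indicators=list(self.indicator_map.values()))
        self.n_boot = n_boot
        self.seed = seed

    def fit(self) -> "ServiceMultiplierResults":
        proportions: dict[str, ProportionEstimate] = {}
        estimates: list[MultiplierEstimate] = []
        rng = np.random.default_rng(self.seed)
        for src in sorted(self.registry):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            prop = rds_proportion(
                self.survey, self.indicator_map[src], n_boot=self.n_boot, seed=sub_seed
            )
            proportions[src] = prop
            est = multiplier_estimate(
                MultiplierInput(source_name=src, count=self.registry[src], proportion=prop)
            )
            estimates.append(est)
        return ServiceMultiplierResults(
            model=self,
            proportions=proportions,
            estimates=estimates,
            synthesis=synthesize_median(estimates),
        )


@dataclass
class ServiceMultiplierResults:
    model: ServiceMultiplier
    proportions: dict[str, ProportionEstimate]
    estimates: list[MultiplierEstimate]
    synthesis: MultiplierEstimate

    def to_dict(self) -> dict:
        """JSON-ready report with every single-source estimate and the median."""
        def as_row(e: MultiplierEstimate, n=None, p=None):
            row = {
                "n_hat": e.n_hat,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "degenerate": e.degenerate,
            }
            if n is not None:
                row["count"] = n
            if p is not None:
                row.update(p_hat=p.p_hat, p_ci_low=p.ci_low, p_ci_high=p.ci_high, n_eff=p.n_eff)
            return row

        return {
            "sources": {
                e.source_name: as_row(
                    e, self.model.registry[e.source_name], self.proportions[e.source_name]
                )
                for e in self.estimates
            },
            "median": as_row(self.synthesis),
        }

    def summary(self) -> str:
        lines = [
            "Service / unique-object multiplier estimates",
            "=" * 52,
            f"{'source':<22}{'n':>8}{'p_hat':>9}{'N_hat':>9}{'95% CI':>18}",
        ]
        for e in self.estimates:
            p = self.proportions[e.source_name]
            flag = " *" if e.degenerate else ""
            lines.append(
                f"{e.source_name:<22}{self.model.registry[e.source_name]:>8.0f}"
                f"{p.p_hat:>9.4f}{e.n_hat:>9.0f}"
                f"{f'({e.ci_low:.0f}, {e.ci_high:.0f})':>18}{flag}"
            )
        s = self.synthesis
        lines.append(
            f"{'median synthesis':<22}{'':>8}{'':>9}{s.n_hat:>9.0f}"
            f"{f'({s.ci_low:.0f}, {s.ci_high:.0f})':>18}"
        )
        if any(e.degenerate for e in self.estimates):
            lines.append("* degenerate boundary proportion; interpret with caution")
        return "\n".join(lines)
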