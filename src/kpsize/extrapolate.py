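"""Extrapolation of mapped-unit estimates to census denominators.

The mapped units are a stratified random sample of administrative units. The
fraction of the general population who belong to the key population is pooled
over the sampled units as a ratio of sums,

    p = sum(M_i) / sum(N_i),

computed separately for the min, mid and max estimates (a ratio of sums, not
a mean of per-unit ratios: large units carry their census weight). The pooled
proportion is then applied to the census population of every unit, district,
province and the nation, so rollups are conserved exactly before rounding.
Plausibility of the linear assumption (constant proportion across units) is
diagnosed with the coefficient of determination of mapped size on census
population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError, SchemaError
from .frame import validate_census
from .mapping import SizeInterval
from .util import round_half_up

__all__ = [
    "PooledProportion",
    "pooled_proportion",
    "extrapolate",
    "linearity_diagnostic",
    "prevalence",
    "Extrapolation",
    "ExtrapolationResults",
]


@dataclass(frozen=True)
class PooledProportion:
    """Pooled KP fraction of the general population (min, mid, max)."""

    p_low: float
    p_mid: float
    p_high: float

    def __post_init__(self):
        if not (0.0 <= self.p_low <= self.p_mid <= self.p_high <= 1.0):
            raise EstimationError(
                f"pooled proportions not ordered in [0,1]: "
                f"({self.p_low}, {self.p_mid}, {self.p_high})"
            )


def _estimates_frame(estimates: Iterable[SizeInterval] | pd.DataFrame) -> pd.DataFrame:
    """Normalise unit estimates into a frame indexed by unit_id."""
    if isinstance(estimates, pd.DataFrame):
        missing = [c for c in ("min", "mid", "max") if c not in estimates.columns]
        if missing:
            raise SchemaError(f"estimates table missing column(s): {missing}")
        return estimates
    rows = {e.key: (e.min, e.mid, e.max) for e in estimates}
    return pd.DataFrame.from_dict(rows, orient="index", columns=["min", "mid", "max"])


def _census_pops(est: pd.DataFrame, census: pd.DataFrame, denominator: str) -> np.ndarray:
    validate_census(census)
    pops = census.set_index("unit_id")[denominator]
    missing = [u for u in est.index if u not in pops.index]
    if missing:
        raise EstimationError(f"no census match for sampled unit(s): {missing[:5]}")
    return pops.loc[est.index].to_numpy(dtype=float)


def pooled_proportion(
    estimates: Iterable[SizeInterval] | pd.DataFrame,
    census: pd.DataFrame,
    denominator: str = "total_pop",
) -> PooledProportion:
    """Pool sampled-unit estimates against their census populations.

    p = sum(M_i)/sum(N_i) for the min, mid and max columns separately.
    """
    est = _estimates_frame(estimates)
    pops = _census_pops(est, census, denominator)
    if (pops <= 0).any():
        raise EstimationError("every sampled unit needs a positive census population")
    total = pops.sum()
    return PooledProportion(
        p_low=float(est["min"].sum() / total),
        p_mid=float(est["mid"].sum() / total),
        p_high=float(est["max"].sum() / total),
    )


def extrapolate(
    p: PooledProportion,
    census: pd.DataFrame,
    level: str,
    denominator: str = "total_pop",
) -> pd.DataFrame:
    """Apply a pooled proportion to census denominators at one level.

    ``level`` is one of ``unit, district, province, national``. Returns a
    tidy frame with columns ``level, key, min, mid, max``; district estimates
    sum to the national estimate exactly (pre-rounding).
    """
    validate_census(census)
    if level == "unit":
        keys, pops = census["unit_id"], census[denominator]
    elif level in ("district", "province"):
        g = census.groupby(level)[denominator].sum()
        keys, pops = g.index, g
    elif level == "national":
        keys, pops = pd.Index(["all"]), pd.Series([census[denominator].sum()])
    else:
        raise EstimationError(
            f"unknown level {level!r}; expected unit/district/province/national"
        )
    pops = np.asarray(pops, dtype=float)
    return pd.DataFrame(
        {
            "level": level,
            "key": np.asarray(keys).astype(str),
            "min": p.p_low * pops,
            "mid": p.p_mid * pops,
            "max": p.p_high * pops,
        }
    )


def linearity_diagnostic(
    estimates: Iterable[SizeInterval] | pd.DataFrame,
    census: pd.DataFrame,
    denominator: str = "total_pop",
    through_origin: bool = False,
) -> float:
    """R-squared of mapped mid-estimates on census populations.

    Default: ordinary least squares with an intercept (the squared Pearson
    correlation). ``through_origin=True`` fits the proportional model the
    extrapolation actually assumes and reports the uncentred R-squared.
    """
    est = _estimates_frame(estimates)
    if len(est) < 3:
        raise EstimationError("linearity diagnostic needs at least 3 sampled units")
    pops = _census_pops(est, census, denominator)
    if np.ptp(pops) == 0:
        raise EstimationError("census populations have zero variance; R^2 undefined")
    y = est["mid"].to_numpy(dtype=float)
    if not through_origin and np.ptp(y) == 0:
        return 0.0  # constant estimates explain nothing; avoid 0/0 in the TSS
    x = pops if through_origin else sm.add_constant(pops)
    return float(sm.OLS(y, x).fit().rsquared)


def prevalence(estimate: SizeInterval, denominator: float) -> tuple[float, float, float]:
    """KP members per 100 of a reference population (e.g. adult females)."""
    if denominator <= 0:
        raise EstimationError(f"prevalence denominator must be positive, got {denominator}")
    return tuple(100.0 * v / denominator for v in (estimate.min, estimate.mid, estimate.max))


class Extrapolation:
    """Census-anchored extrapolation model.

    Built from per-unit size estimates for the *sampled* units and the full
    national census table; ``fit`` pools the proportion, projects it to every
    administrative level and computes the linearity diagnostic.

    ``stratum_weighted=True`` enables a sensitivity mode that pools each
    density stratum separately and combines them by census share. This
    corrects for the deliberate oversampling of high-density strata but
    departs from the simple pooled ratio used for the headline estimates.
    """

    def __init__(
        self,
        unit_estimates: Iterable[SizeInterval] | pd.DataFrame,
        census: pd.DataFrame,
        denominator: str = "total_pop",
        stratum_weighted: bool = False,
    ):
        self.unit_estimates = _estimates_frame(unit_estimates)
        self.census = validate_census(census)
        self.denominator = denominator
        self.stratum_weighted = stratum_weighted

    def _pool(self) -> PooledProportion:
        if not self.stratum_weighted:
            return pooled_proportion(self.unit_estimates, self.census, self.denominator)
        import warnings

        from .frame import stratify_units

        warnings.warn(
            "stratum-weighted pooling is a sensitivity mode; the headline method "
            "uses the simple pooled ratio over all sampled units",
            stacklevel=2,
        )
        strata = stratify_units(self.census).set_index("unit_id")["stratum"]
        pops = self.census.set_index("unit_id")[self.denominator]
        share = pops.groupby(strata).sum() / pops.sum()
        p = np.zeros(3)
        for name, frac in share.items():
            members = strata.index[strata == name]
            sampled = self.unit_estimates.index.intersection(members)
            if len(sampled) == 0:
                raise EstimationError(f"no sampled units in stratum {name!r}")
            ps = pooled_proportion(
                self.unit_estimates.loc[sampled], self.census, self.denominator
            )
            p += frac * np.array([ps.p_low, ps.p_mid, ps.p_high])
        return PooledProportion(*p)

    def fit(self) -> "ExtrapolationResults":
        pooled = self._pool()
        tables = {
            level: extrapolate(pooled, self.census, level, self.denominator)
            for level in ("unit", "district", "province", "national")
        }
        r2 = linearity_diagnostic(self.unit_estimates, self.census, self.denominator)
        return ExtrapolationResults(model=self, pooled=pooled, tables=tables, r_squared=r2)


@dataclass
class ExtrapolationResults:
    model: Extrapolation
    pooled: PooledProportion
    tables: dict[str, pd.DataFrame]
    r_squared: float

    @property
    def national(self) -> SizeInterval:
        row = self.tables["national"].iloc[0]
        return SizeInterval("national", "all", row["min"], row["mid"], row["max"])

    def tidy(self) -> pd.DataFrame:
        """All levels stacked into one tidy frame (level, key, min, mid, max)."""
        return pd.concat(self.tables.values(), ignore_index=True)

    def prevalence_pct(self, denominator_col: str = "adult_f") -> tuple[float, float, float]:
        """National estimate as a percentage of a census adult denominator."""
        return prevalence(self.national, float(self.model.census[denominator_col].sum()))

    def plot_linearity(self, ax=None):
        """Scatter of unit mid-estimates against census population with the
        fitted least-squares line (the diagnostic behind ``r_squared``)."""
        import matplotlib.pyplot as plt

        est = self.model.unit_estimates
        pops = _census_pops(est, self.model.census, self.model.denominator)
        y = est["mid"].to_numpy(dtype=float)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(pops, y, s=18)
        beta = sm.OLS(y, sm.add_constant(pops)).fit().params
        xs = np.linspace(pops.min(), pops.max(), 50)
        ax.plot(xs, beta[0] + beta[1] * xs, color="C1")
        ax.set_xlabel("census population of unit")
        ax.set_ylabel("mapped mid-estimate")
        ax.set_title(f"linearity diagnostic, $R^2$ = {self.r_squared:.3f}")
        return ax

    def summary(self) -> str:
        lo, mid, hi = self.national.rounded()
        lines = [
            "Census-anchored extrapolation",
            "=" * 45,
            f"Sampled units: {len(self.model.unit_estimates)}",
            f"Pooled proportion (mid): {self.pooled.p_mid:.6f} "
            f"[{self.pooled.p_low:.6f}, {self.pooled.p_high:.6f}]",
            f"Linearity R^2: {self.r_squared:.3f}",
            f"National estimate: {mid}  (range {lo}-{hi})",
        ]
        return "\n".join(lines)
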