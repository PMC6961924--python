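"""Sampling frame: density stratification of administrative units and the
stratified random draw of units to map.

The mapping stage cannot visit every administrative unit, so units are ranked
by total census population, cut into three contiguous density terciles
(high / medium / low), and a fixed fraction of each stratum is drawn at
random — deliberately oversampling the high-density stratum where key
populations concentrate.

The census table is a plain :class:`pandas.DataFrame` with columns

    unit_id, district, province, total_pop, adult_f, adult_m

(see :func:`kpsize.io.read_census` for reading a CSV with other headers).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, SchemaError
from .util import check_probability, check_unique, round_half_up

STRATA = ("high", "medium", "low")

CENSUS_COLUMNS = ("unit_id", "district", "province", "total_pop", "adult_f", "adult_m")

__all__ = ["STRATA", "CENSUS_COLUMNS", "validate_census", "stratify_units", "select_units"]


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    """Check the census table schema; returns the frame untouched."""
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise SchemaError(f"census table missing column(s): {missing}")
    check_unique(census["unit_id"], "unit_id in census table")
    for col in ("total_pop", "adult_f", "adult_m"):
        bad = census.index[census[col] < 0]
        if len(bad):
            raise SchemaError(f"census column {col!r} negative at rows {list(bad[:5])}")
    return census


def stratify_units(census: pd.DataFrame) -> pd.DataFrame:
    """Assign every unit to a population-density tercile.

    Units are sorted by ``total_pop`` descending (ties broken by ``unit_id``
    ascending for determinism) and cut into three contiguous groups whose
    sizes differ by at most one; any remainder goes to the *low* end, so 331
    units split 110 / 110 / 111. The largest populations form the ``high``
    stratum.

    Returns a frame with columns ``unit_id, stratum``.
    """
    validate_census(census)
    n = len(census)
    if n < 3:
        raise EstimationError(f"need at least 3 units to form terciles, got {n}")
    ordered = census.sort_values(
        ["total_pop", "unit_id"], ascending=[False, True], kind="mergesort"
    )["unit_id"].to_numpy()
    base, rem = divmod(n, 3)
    sizes = [base, base, base]
    for i in range(rem):  # remainder accrues from the low end
        sizes[2 - i] += 1
    labels = np.repeat(STRATA, sizes)
    return pd.DataFrame({"unit_id": ordered, "stratum": labels})


def select_units(
    assignment: pd.DataFrame,
    fractions: Mapping[str, float] | Sequence[float],
    seed: int,
) -> list:
    """Draw the stratified random sample of units to be mapped.

    Parameters
    ----------
    assignment
        Output of :func:`stratify_units` (columns ``unit_id, stratum``).
    fractions
        Per-stratum sampling fraction, either a mapping keyed by stratum
        name or a sequence ordered (high, medium, low). Each in [0, 1].
    seed
        RNG seed; the draw is without replacement and reproducible, and is
        invariant to the row order of ``assignment``.

    Per-stratum sample sizes are ``round_half_up(fraction * stratum_size)``,
    e.g. 25% of 110 -> 28.
    """
    if not isinstance(fractions, Mapping):
        fractions = dict(zip(STRATA, fractions))
    for name in STRATA:
        check_probability(fractions.get(name, 0.0), f"fraction[{name}]")
    rng = np.random.default_rng(seed)
    selected: list = []
    for name in STRATA:  # fixed stratum order for determinism
        members = np.sort(
            assignment.loc[assignment["stratum"] == name, "unit_id"].to_numpy()
        )
        k = round_half_up(float(fractions.get(name, 0.0)) * len(members))
        k = min(int(k), len(members))
        if k:
            selected.extend(rng.choice(members, size=k, replace=False).tolist())
    return selected
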