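"""CSV / YAML / JSON input-output.

All tables travel as RFC-4180 UTF-8 CSV. Column headers can be remapped via a
YAML mapping file (``their_name: our_name``) so field exports do not need to
be renamed by hand. Readers fail fast with :class:`~kpsize.errors.SchemaError`
naming the offending column or row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .delphi import DENSITY_CODES, DelphiBallot
from .errors import SchemaError
from .frame import validate_census
from .mapping import AdjustmentParams, validate_spots
from .multiplier import validate_survey

__all__ = [
    "read_census",
    "read_spots",
    "read_survey",
    "read_registry",
    "read_ballots",
    "read_adjustment_params",
    "write_json",
]


def _read_csv(path, colmap: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if colmap:
        df = df.rename(columns=dict(colmap))
    return df


def read_census(path, colmap: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Read and validate a census table (unit_id, district, province,
    total_pop, adult_f, adult_m)."""
    return validate_census(_read_csv(path, colmap))


def read_spots(path, colmap: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Read and validate a Level-2 spot table."""
    return validate_spots(_read_csv(path, colmap))


def read_survey(
    path,
    indicators: Sequence[str] = (),
    colmap: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read and validate an RDS survey table (seeds have empty recruiter_id)."""
    # ids parsed as strings so "248" never becomes 248.0 via a NaN column
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if colmap:
        df = df.rename(columns=dict(colmap))
    for col in df.columns:
        if col in ("respondent_id", "recruiter_id"):
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return validate_survey(df, indicators=indicators)


def read_registry(path, colmap: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Read service-registry counts.

    Two layouts are accepted:

    * aggregated — columns ``source_name, count`` (optionally
      ``period_start, period_end``), one row per source;
    * client-level — columns ``source_name, client_code``, one row per
      client contact. Client codes must already be de-duplicated within a
      source; a repeated code is a hard error, not silently collapsed,
      because a duplicate means the upstream de-duplication failed.

    Returns the aggregated layout either way.
    """
    df = _read_csv(path, colmap)
    if "count" in df.columns:
        if "source_name" not in df.columns:
            raise SchemaError("registry table missing column 'source_name'")
        return df[["source_name", "count"]]
    if {"source_name", "client_code"} <= set(df.columns):
        for src, g in df.groupby("source_name"):
            dup = g["client_code"][g["client_code"].duplicated()]
            if len(dup):
                raise SchemaError(
                    f"registry source {src!r} has duplicate client code(s): "
                    f"{sorted(dup.unique())[:5]} — de-duplicate upstream"
                )
        agg = df.groupby("source_name").size().rename("count").reset_index()
        return agg
    raise SchemaError(
        "registry table needs either (source_name, count) or (source_name, client_code)"
    )


def read_ballots(path, colmap: Optional[Mapping[str, str]] = None) -> list[DelphiBallot]:
    """Read Delphi ballots: one row per participant, columns
    ``participant_id, most_likely, lower, upper`` plus optional
    ``density_<district>`` columns with low/medium/high values."""
    df = _read_csv(path, colmap)
    needed = ["participant_id", "most_likely", "lower", "upper"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"ballot table missing column(s): {missing}")
    density_cols = [c for c in df.columns if c.startswith("density_")]
    ballots = []
    for _, row in df.iterrows():
        density = {}
        for c in density_cols:
            val = row[c]
            if pd.isna(val) or val == "":
                continue
            val = str(val).strip().lower()
            if val not in DENSITY_CODES:
                raise SchemaError(
                    f"ballot {row['participant_id']!r}: density value {val!r} in {c!r} "
                    f"must be one of {sorted(DENSITY_CODES)}"
                )
            density[c.removeprefix("density_")] = val
        ballots.append(
            DelphiBallot(
                participant_id=str(row["participant_id"]),
                most_likely=float(row["most_likely"]),
                lower=float(row["lower"]),
                upper=float(row["upper"]),
                district_density=density,
            )
        )
    return ballots


def read_adjustment_params(path) -> AdjustmentParams:
    """Read mobility/hidden adjustment parameters from YAML
    (keys ``p1, m1, p2``; ``p2`` may be a region -> fraction mapping)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a YAML mapping with keys p1, m1, p2")
    return AdjustmentParams(**raw)


def write_json(obj, path) -> Path:
    """Deterministic JSON writer (sorted keys, trailing newline)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
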