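"""Small shared numerics: reporting rounds and validation helpers."""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = ["round_half_up", "check_probability", "check_unique"]


def round_half_up(x: float | Iterable[float]):
    """Round to the nearest integer with exact halves going up.

    Used only at the reporting boundary: all internal counts stay real.
    ``round_half_up(27.5) == 28``, unlike banker's rounding.
    """
    if np.ndim(x) == 0:
        return int(math.floor(float(x) + 0.5))
    arr = np.asarray(x, dtype=float)
    return np.floor(arr + 0.5).astype(int)


def check_probability(value: float, name: str, *, allow_one: bool = True) -> float:
    """Validate a probability-like parameter, returning it unchanged."""
    from .errors import ConfigurationError

    v = float(value)
    if not (0.0 <= v <= 1.0) or (not allow_one and v == 1.0):
        hi = "1" if allow_one else "1)"
        lo = "[0, " + hi if allow_one else "[0, 1)"
        raise ConfigurationError(f"{name}={value!r} must lie in {lo}")
    return v


def check_unique(values, what: str) -> None:
    """Raise SchemaError naming the duplicated keys if ``values`` repeat."""
    from .errors import SchemaError

    import pandas as pd

    s = pd.Series(list(values))
    dup = s[s.duplicated()].unique()
    if len(dup):
        raise SchemaError(f"duplicate {what}: {sorted(map(str, dup))[:10]}")
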