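"""Simple qualification degree: piecewise deviation-from-limit scoring.

Each inspection record carries a test result ``T`` and a permissible-limit
pair ``(min_limit, max_limit)``.  The limit pair classifies into one of four
scoreable kinds (plus a reserved ``min_only`` kind for records without an
upper limit, which are excluded from scoring), and the score ``Q`` in [0, 1]
measures how far the result sits from the offending bound: 1 is safest, 0 is
non-qualified.

Two of the piecewise branches admit more than one algebraic reading; the
parses used here are:

* point limit (``0 < min == max``): ``Q = 2 - T/min`` clamped to [0, 1] —
  value 1 at ``T == min``, falling to 0 at ``T == 2*min``;
* band limit (``0 < min < max``): ``Q = 1 - |(T - min)/(max - min) - 0.5|``
  — maximal (1) at the band midpoint, 0.5 at either edge.

Both choices keep ``Q`` inside [0, 1] for every admissible input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidLimitError, InvalidMeasurementError, MissingLimitError

__all__ = [
    "LimitKind",
    "LimitSpec",
    "classify_limit",
    "simple_qualification_degree",
    "is_out_of_bound",
    "score_records",
]


class LimitKind(str, Enum):
    """Branch classes of the qualification score."""

    MAX_ONLY = "max_only"
    MIN_ONLY = "min_only"  # no upper limit: not scoreable, record excluded
    BAND = "band"
    EXACT_ZERO = "exact_zero"
    POINT = "point"


def classify_limit(min_limit: float, max_limit: float) -> LimitKind:
    """Classify a (min, max) permissible-limit pair into its branch class.

    The classification is a pure function of the pair:

    ========================  ===========
    condition                 kind
    ========================  ===========
    ``0 == min < max``        max_only
    ``0 < min == max``        point
    ``0 < min < max``         band
    ``0 == min == max``       exact_zero
    ========================  ===========

    Raises
    ------
    InvalidLimitError
        If ``min_limit > max_limit`` or either bound is negative/non-finite.
    """
    if not (math.isfinite(min_limit) and math.isfinite(max_limit)):
        raise InvalidLimitError(f"non-finite limits ({min_limit}, {max_limit})")
    if min_limit < 0 or max_limit < 0:
        raise InvalidLimitError(f"negative limit in ({min_limit}, {max_limit})")
    if min_limit > max_limit:
        raise InvalidLimitError(
            f"min_limit {min_limit} exceeds max_limit {max_limit}"
        )
    if min_limit == 0 and max_limit == 0:
        return LimitKind.EXACT_ZERO
    if min_limit == max_limit:
        return LimitKind.POINT
    if min_limit == 0:
        return LimitKind.MAX_ONLY
    return LimitKind.BAND


@dataclass(frozen=True)
class LimitSpec:
    """A validated permissible-limit pair with its derived branch class."""

    min_limit: float
    max_limit: float
    kind: LimitKind = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "kind", classify_limit(self.min_limit, self.max_limit)
        )


def simple_qualification_degree(test_result: float, limits: LimitSpec) -> float:
    """Score one test result against its limits; returns ``Q`` in [0, 1].

    Raises
    ------
    InvalidMeasurementError
        If ``test_result`` is negative or non-finite.
    """
    T = float(test_result)
    if not math.isfinite(T) or T < 0:
        raise InvalidMeasurementError(f"invalid test result {test_result!r}")
    mn, mx = limits.min_limit, limits.max_limit
    kind = limits.kind
    if kind is LimitKind.EXACT_ZERO:
        return 1.0 if T == 0 else 0.0
    if kind is LimitKind.MAX_ONLY:
        return 1.0 - T / mx if T < mx else 0.0
    if kind is LimitKind.POINT:
        if T < mn:
            return 0.0
        return min(1.0, max(0.0, 2.0 - T / mn))
    if kind is LimitKind.BAND:
        if T < mn or T >= mx:
            return 0.0
        return 1.0 - abs((T - mn) / (mx - mn) - 0.5)
    raise MissingLimitError("record has no upper permissible limit")


def is_out_of_bound(test_result: float, limits: LimitSpec) -> bool:
    """True when the result is non-qualified under its branch conditions.

    ``Q == 0`` exactly on these inputs.
    """
    T = float(test_result)
    mn, mx = limits.min_limit, limits.max_limit
    kind = limits.kind
    if kind is LimitKind.EXACT_ZERO:
        return T != 0
    if kind is LimitKind.MAX_ONLY:
        return T >= mx
    if kind is LimitKind.POINT:
        # mirror the scoring arithmetic so Q == 0 iff out-of-bound holds
        # exactly even under floating-point rounding of T / mn
        return T < mn or 2.0 - T / mn <= 0.0
    if kind is LimitKind.BAND:
        return T < mn or T >= mx
    raise MissingLimitError("record has no upper permissible limit")


def _q_vectorized(
    T: np.ndarray, mn: np.ndarray, mx: np.ndarray
) -> np.ndarray:
    """Vectorized scorer over valid (T, min, max) triples."""
    q = np.zeros_like(T, dtype=float)

    exact_zero = (mn == 0) & (mx == 0)
    q[exact_zero & (T == 0)] = 1.0

    max_only = (mn == 0) & (mx > 0)
    sel = max_only & (T < mx)
    q[sel] = 1.0 - T[sel] / mx[sel]

    point = (mn > 0) & (mn == mx)
    sel = point & (T >= mn)
    q[sel] = np.clip(2.0 - T[sel] / mn[sel], 0.0, 1.0)

    band = (mn > 0) & (mn < mx)
    sel = band & (T >= mn) & (T < mx)
    q[sel] = 1.0 - np.abs((T[sel] - mn[sel]) / (mx[sel] - mn[sel]) - 0.5)

    return q


def score_records(
    records: pd.DataFrame,
    *,
    result_col: str = "test_result",
    min_col: str = "min_limit",
    max_col: str = "max_limit",
    q_col: str = "Q",
) -> tuple[pd.DataFrame, list[str]]:
    """Score a records table, appending a ``Q`` column.

    Empty min-limit cells are read as 0 (no lower limit); rows with an empty
    max-limit cell have no scoreable limit and are excluded.  Returns the
    scored table (excluded rows dropped) and an exclusion log, one line per
    dropped row.
    """
    df = records.copy()
    log: list[str] = []

    mn = pd.to_numeric(df[min_col], errors="coerce").fillna(0.0).to_numpy(float)
    mx = pd.to_numeric(df[max_col], errors="coerce").to_numpy(float)
    T = pd.to_numeric(df[result_col], errors="coerce").to_numpy(float)

    missing = np.isnan(mx)
    bad_limit = ~missing & ((mn < 0) | (mx < 0) | (mn > mx))
    bad_result = np.isnan(T) | (T < 0)

    drop = missing | bad_limit | bad_result
    if drop.any():
        sample_ids = (
            df["sample_id"].astype(str).to_numpy()
            if "sample_id" in df.columns
            else df.index.astype(str).to_numpy()
        )
        for pos in np.nonzero(drop)[0]:
            if missing[pos]:
                reason = "missing max limit"
            elif bad_limit[pos]:
                reason = "invalid limit pair"
            else:
                reason = "invalid test result"
            log.append(f"excluded sample {sample_ids[pos]}: {reason}")

    keep = ~drop
    out = df.loc[keep].copy()
    out[q_col] = _q_vectorized(T[keep], mn[keep], mx[keep])
    return out, log


def score_many(
    triples: Iterable[tuple[float, float, float]]
) -> np.ndarray:
    """Score an iterable of valid (T, min, max) triples. Test/benchmark helper."""
    arr = np.asarray(list(triples), dtype=float)
    return _q_vectorized(arr[:, 0], arr[:, 1], arr[:, 2])
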