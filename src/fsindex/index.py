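"""Comprehensive qualification degree and the 0-100 safety index reports.

The comprehensive degree of one sample is the product of its simple
qualification score with the consumption, hazard, channel, region, and
factor-correction weights.  The expert-elicitation baseline is the same
product with the factor-correction weight fixed to 1.  Group means by city
or food category give the raw report, which is min-max scaled across units
to a 0-100 index (all-equal or single-unit reports map to 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyReportError, InvalidParameterError, MissingWeightError

__all__ = [
    "comprehensive_degree",
    "expert_baseline_degree",
    "aggregate",
    "scale_index",
    "IndexReport",
    "build_report",
]


def _validate(Q, *weights) -> None:
    Q = np.asarray(Q, dtype=float)
    if np.any(np.isnan(Q)) or np.any(Q < 0) or np.any(Q > 1):
        raise InvalidParameterError("Q must lie in [0, 1]")
    for w in weights:
        w = np.asarray(w, dtype=float)
        if np.any(np.isnan(w)):
            raise MissingWeightError("missing weight value (NaN)")
        if np.any(w <= 0):
            raise InvalidParameterError("weights must be positive")


def comprehensive_degree(Q, wc, wh, ws, wr, wfadm):
    """Product ``wc * wh * ws * wr * wfadm * Q``; scalar or elementwise."""
    _validate(Q, wc, wh, ws, wr, wfadm)
    out = (
        np.asarray(wc, float)
        * np.asarray(wh, float)
        * np.asarray(ws, float)
        * np.asarray(wr, float)
        * np.asarray(wfadm, float)
        * np.asarray(Q, float)
    )
    return float(out) if out.ndim == 0 else out


def expert_baseline_degree(Q, wc, wh, ws, wr):
    """Expert-elicitation baseline: the same product without the factor weight."""
    return comprehensive_degree(Q, wc, wh, ws, wr, 1.0)


def aggregate(q_bar, groups) -> tuple[dict[str, float], dict[str, int]]:
    """Arithmetic mean of per-sample degrees by group label.

    Returns (group -> mean, group -> count).  Groups with zero samples are
    simply absent.

    Raises
    ------
    EmptyReportError
        On empty input.
    """
    q = pd.Series(np.asarray(q_bar, dtype=float))
    g = pd.Series(list(groups))
    if len(q) == 0:
        raise EmptyReportError("no scored samples to aggregate")
    if len(q) != len(g):
        raise InvalidParameterError("q_bar and groups length mismatch")
    grouped = q.groupby(g.values)
    means = {str(k): float(v) for k, v in grouped.mean().items()}
    counts = {str(k): int(v) for k, v in grouped.size().items()}
    return means, counts


def scale_index(per_unit_raw: Mapping[str, float]) -> dict[str, float]:
    """Min-max scale raw group means across units to [0, 100].

    The unit order and ties are preserved; a single-unit or all-equal report
    maps every unit to 100.
    """
    if not per_unit_raw:
        raise EmptyReportError("empty report")
    vals = np.array(list(per_unit_raw.values()), dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return {u: 100.0 for u in per_unit_raw}
    span = hi - lo
    # divide before scaling and clamp: guards 1-ulp overshoot past 100
    return {
        u: min(100.0, max(0.0, 100.0 * ((float(v) - lo) / span)))
        for u, v in per_unit_raw.items()
    }


@dataclass
class IndexReport:
    """Per-unit raw means and scaled indexes for one grouping and method."""

    method: Literal["fadm", "expert"]
    grouping: Literal["city", "category"]
    per_unit_raw: dict[str, float]
    per_unit_index: dict[str, float]
    n_samples: dict[str, int]
    stratum: str | None = None

    def to_frame(self) -> pd.DataFrame:
        units = sorted(self.per_unit_raw)
        return pd.DataFrame(
            {
                "unit": units,
                "grouping": self.grouping,
                "method": self.method,
                "n": [self.n_samples[u] for u in units],
                "raw_mean": [self.per_unit_raw[u] for u in units],
                "scaled_index": [self.per_unit_index[u] for u in units],
                "stratum": self.stratum if self.stratum is not None else "",
            }
        )


def build_report(
    q_bar,
    groups,
    *,
    method: str,
    grouping: str,
    scaling: Literal["minmax", "raw"] = "minmax",
    stratum: str | None = None,
) -> IndexReport:
    """Aggregate per-sample degrees into an :class:`IndexReport`."""
    raw, counts = aggregate(q_bar, groups)
    if scaling == "minmax":
        idx = scale_index(raw)
    elif scaling == "raw":
        idx = {u: float(v) for u, v in raw.items()}
    else:
        raise InvalidParameterError(f"unknown scaling mode {scaling!r}")
    return IndexReport(
        method=method,  # type: ignore[arg-type]
        grouping=grouping,  # type: ignore[arg-type]
        per_unit_raw=raw,
        per_unit_index=idx,
        n_samples=counts,
        stratum=stratum,
    )
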