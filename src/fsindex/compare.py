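"""Paired-sample t comparison between two index series.

``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = x - y`` and the n-1
denominator in the standard deviation; the two-sided p-value comes from the
t distribution with n-1 degrees of freedom.  Zero-variance differences are
handled explicitly so the comparison is total: identical series give p = 1,
a constant nonzero shift gives p = 0, both with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AlignmentError, InsufficientDataError

__all__ = ["ComparisonResult", "paired_t"]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    t_stat: float
    p_value: float
    n: int
    mean_diff: float
    sd_diff: float
    warnings: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        """True when p < 0.05 (the difference is significant)."""
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "t": self.t_stat,
            "p": self.p_value,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "alpha": ALPHA,
            "verdict": "significant" if self.significant else "not significant",
            "warnings": list(self.warnings),
        }


def paired_t(x, y) -> ComparisonResult:
    """Two-sided paired t-test of two aligned series.

    Raises
    ------
    AlignmentError
        Length mismatch.
    InsufficientDataError
        Fewer than 2 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError(
            f"series must be 1-d and aligned, got shapes {x.shape} and {y.shape}"
        )
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")

    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    notes: list[str] = []
    if sd == 0.0:
        if mean == 0.0:
            msg = "zero variance and zero mean difference: p set to 1"
            t, p = 0.0, 1.0
        else:
            msg = "zero variance with nonzero mean difference: p set to 0"
            t, p = math.copysign(math.inf, mean), 0.0
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    else:
        t = mean / (sd / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return ComparisonResult(t, p, n, mean, sd, notes)
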