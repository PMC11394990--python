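"""Factor analysis of mixed data and the per-sample factor correction weight.

The mixed design holds a standardized quantitative block and a centered
one-hot indicator block for the qualitative variables.  Each block is
divided by its first eigenvalue (the top eigenvalue of ``block.T @ block / n``)
before the blocks are concatenated and decomposed by SVD:

    G = [ X1/lambda1_quant | Xind/lambda1_qual ] = U S V^T

Factor scores are ``F = sqrt(n) * U S`` (the inverse square root of the
uniform 1/n mass matrix applied to U S), and the variance contribution of
factor i is ``s_i^2 / sum(s_j^2)``.

Raw factor scores are deviations from the mean, so before entering the
composite weight they pass through a bounded exponential transform with
ceiling ``k``: monotone increasing, range (1, k), value ``(k+1)/2`` at 0.
The per-sample correction weight is the contribution-weighted mean of the
transformed scores over the retained factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidParameterError,
    RetentionError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MixedDesign",
    "Retention",
    "FadmParams",
    "FactorModel",
    "encode_mixed",
    "first_eigenvalue",
    "famd_decompose",
    "transform_score",
    "fadm_weight",
]


@dataclass
class MixedDesign:
    """Preprocessed design: standardized numeric block + centered indicators.

    ``quantitative`` is n x p1 (each column centered, unit variance);
    ``indicator`` is n x m with one centered 0/1 column per observed level
    of each qualitative variable.  ``dropped`` logs the variables and levels
    removed during preprocessing.
    """

    quantitative: np.ndarray
    quantitative_names: list[str]
    indicator: np.ndarray
    indicator_names: list[str]
    n: int
    dropped: list[str] = field(default_factory=list)

    @property
    def p1(self) -> int:
        return self.quantitative.shape[1]

    @property
    def m(self) -> int:
        return self.indicator.shape[1]


@dataclass(frozen=True)
class Retention:
    """Factor-retention rule.

    ``cumulative_variance`` keeps the smallest r whose contributions sum to
    at least ``value``; ``kaiser`` keeps factors whose eigenvalue
    (``s^2 / n``) exceeds 1; ``fixed`` keeps exactly ``value`` factors.
    """

    rule: Literal["cumulative_variance", "kaiser", "fixed"] = "cumulative_variance"
    value: float = 0.80

    def __post_init__(self) -> None:
        if self.rule == "cumulative_variance" and not (0 < self.value <= 1):
            raise InvalidParameterError(
                f"cumulative-variance threshold {self.value} outside (0, 1]"
            )
        if self.rule == "fixed" and (self.value < 1 or self.value != int(self.value)):
            raise InvalidParameterError(f"fixed retention needs an integer >= 1")

    @classmethod
    def parse(cls, text: str) -> "Retention":
        """Parse ``'cumulative:0.8'``, ``'kaiser'`` or ``'fixed:3'``."""
        rule, _, val = text.partition(":")
        rule = rule.strip().lower()
        if rule in ("cumulative", "cumulative_variance"):
            return cls("cumulative_variance", float(val) if val else 0.80)
        if rule == "kaiser":
            return cls("kaiser", 0.0)
        if rule == "fixed":
            if not val:
                raise InvalidParameterError("fixed retention needs a count, e.g. fixed:3")
            return cls("fixed", int(val))
        raise InvalidParameterError(f"unknown retention rule {text!r}")


@dataclass(frozen=True)
class FadmParams:
    """Transform ceiling and retention rule for the factor weight."""

    k: float = 100.0
    retention: Retention = field(default_factory=Retention)
    orientation: Literal["increasing", "decreasing"] = "increasing"

    def __post_init__(self) -> None:
        if self.k <= 1:
            raise InvalidParameterError(f"transform ceiling k={self.k} must exceed 1")


@dataclass
class FactorModel:
    """SVD factorization of the block-scaled mixed design."""

    lambda1_quant: float | None
    lambda1_qual: float | None
    left_vectors: np.ndarray       # U, n x r_full, orthonormal columns
    singular_values: np.ndarray    # non-increasing, non-negative
    right_vectors: np.ndarray      # V, p x r_full, orthonormal columns
    factor_scores: np.ndarray      # F = sqrt(n) U S, n x r_full
    variance_contributions: np.ndarray  # fractions over ALL factors, sum 1
    n_retained: int
    n: int

    @property
    def mass(self) -> np.ndarray:
        """Uniform diagonal mass matrix entries (1/n per sample)."""
        return np.full(self.n, 1.0 / self.n)


def encode_mixed(
    records: pd.DataFrame,
    quantitative: Sequence[str],
    qualitative: Sequence[str],
) -> MixedDesign:
    """Encode a records table into a preprocessed mixed design.

    Quantitative columns are standardized (population std); qualitative
    columns are expanded into one-hot indicators which are then centered.
    Constant quantitative columns and single-level qualitative variables are
    dropped and logged.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 rows.
    DegenerateInputError
        No usable column survives preprocessing.
    """
    n = len(records)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {n}")

    dropped: list[str] = []

    quant_cols: list[np.ndarray] = []
    quant_names: list[str] = []
    for name in quantitative:
        col = pd.to_numeric(records[name], errors="coerce").to_numpy(float)
        if np.isnan(col).any():
            raise DegenerateInputError(f"non-numeric values in quantitative {name!r}")
        sd = col.std()  # population (ddof=0) so a unit column has lambda1 = 1
        if sd == 0:
            dropped.append(f"quantitative {name!r}: constant column")
            continue
        quant_cols.append((col - col.mean()) / sd)
        quant_names.append(name)

    ind_cols: list[np.ndarray] = []
    ind_names: list[str] = []
    for name in qualitative:
        labels = records[name].astype(str)
        levels = labels.unique()
        if len(levels) < 2:
            dropped.append(f"qualitative {name!r}: single observed level")
            continue
        onehot = pd.get_dummies(labels)
        for level in sorted(onehot.columns):
            col = onehot[level].to_numpy(float)
            ind_cols.append(col - col.mean())
            ind_names.append(f"{name}={level}")

    for msg in dropped:
        logger.info("encode_mixed dropped %s", msg)

    if not quant_cols and not ind_cols:
        raise DegenerateInputError("no usable variable after preprocessing")

    quant = np.column_stack(quant_cols) if quant_cols else np.empty((n, 0))
    ind = np.column_stack(ind_cols) if ind_cols else np.empty((n, 0))
    return MixedDesign(quant, quant_names, ind, ind_names, n, dropped)


def first_eigenvalue(block: np.ndarray) -> float:
    """Top eigenvalue of ``block.T @ block / n`` = (largest singular value)^2 / n.

    Raises
    ------
    DegenerateInputError
        Zero or empty block.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] == 0:
        raise DegenerateInputError("block has no columns")
    top_sv = np.linalg.svd(block, compute_uv=False)[0]
    lam = top_sv**2 / block.shape[0]
    if lam <= 0:
        raise DegenerateInputError("zero block matrix")
    return float(lam)


def _sign_flip(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-|.| entry of each U column > 0."""
    if U.shape[1] == 0:
        return U, V
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def famd_decompose(design: MixedDesign, params: FadmParams | None = None) -> FactorModel:
    """Scale each block by its first eigenvalue, concatenate, and SVD.

    Returns the factor model with factor scores ``sqrt(n) * U S``, variance
    contributions normalized over all factors, and the retention rule from
    ``params`` applied to fix the number of retained factors.
    """
    params = params or FadmParams()
    blocks: list[np.ndarray] = []
    lam_quant = lam_qual = None
    if design.p1 > 0:
        lam_quant = first_eigenvalue(design.quantitative)
        blocks.append(design.quantitative / lam_quant)
    if design.m > 0:
        lam_qual = first_eigenvalue(design.indicator)
        blocks.append(design.indicator / lam_qual)
    if not blocks:
        raise DegenerateInputError("empty design")

    G = np.hstack(blocks)
    try:
        U, s, Vt = np.linalg.svd(G, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise DegenerateInputError(f"SVD failed: {exc}") from exc
    total = float(np.sum(s**2))
    if total <= 0:
        raise DegenerateInputError("design has no variance")

    U, V = _sign_flip(U, Vt.T)
    F = np.sqrt(design.n) * U * s
    contrib = s**2 / total
    r = _retained(s, contrib, design.n, params.retention)
    return FactorModel(
        lambda1_quant=lam_quant,
        lambda1_qual=lam_qual,
        left_vectors=U,
        singular_values=s,
        right_vectors=V,
        factor_scores=F,
        variance_contributions=contrib,
        n_retained=r,
        n=design.n,
    )


def _retained(
    s: np.ndarray, contrib: np.ndarray, n: int, retention: Retention
) -> int:
    if retention.rule == "cumulative_variance":
        cum = np.cumsum(contrib)
        return min(int(np.searchsorted(cum, retention.value - 1e-12) + 1), len(s))
    if retention.rule == "kaiser":
        r = int(np.sum(s**2 / n > 1.0))
        return max(r, 1)
    return min(int(retention.value), len(s))


def transform_score(
    scores: np.ndarray | float, k: float, orientation: str = "increasing"
) -> np.ndarray | float:
    """Bounded exponential transform of raw factor scores into (1, k).

    For the default increasing orientation::

        f(x) = k - (k-1)/2 * exp(-x)   x >= 0
        f(x) = 1 + (k-1)/2 * exp(x)    x <  0

    Both pieces meet at ``f(0) = (k+1)/2`` and the map is continuous and
    strictly increasing.  The decreasing orientation mirrors the branches
    (an alternative reading of the printed formula).

    Raises
    ------
    InvalidParameterError
        If ``k <= 1`` or orientation is unknown.
    """
    if k <= 1:
        raise InvalidParameterError(f"transform ceiling k={k} must exceed 1")
    x = np.asarray(scores, dtype=float)
    decay = 0.5 * (k - 1.0) * np.exp(-np.abs(x))
    if orientation == "increasing":
        out = np.where(x >= 0, k - decay, 1.0 + decay)
    elif orientation == "decreasing":
        out = np.where(x >= 0, 1.0 + decay, k - decay)
    else:
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    return float(out) if out.ndim == 0 else out


def fadm_weight(model: FactorModel, params: FadmParams | None = None) -> np.ndarray:
    """Per-sample factor correction weight in (1, k).

    For sample s with transformed retained-factor scores ``f_i`` and
    variance contributions ``w_i``::

        weight_s = sum_i f_i(s) * w_i / sum_i w_i

    Raises
    ------
    RetentionError
        If no factor is retained.
    """
    params = params or FadmParams()
    r = model.n_retained
    if r < 1:
        raise RetentionError("no retained factors")
    F = model.factor_scores[:, :r]
    w = model.variance_contributions[:r]
    f = transform_score(F, params.k, params.orientation)
    return np.asarray(f) @ w / w.sum()
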