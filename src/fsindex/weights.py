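"""Consumption, hazard, sales-channel and production-region weights.

All four weights are lookups against configuration tables supplied by the
user (or the synthetic generator): per-capita consumption by food category,
a 1-5 hazard score per test project, a channel -> size-class map, and a
region classification.  Only the consumption weight involves arithmetic
(normalization to proportions); the rest are deterministic table lookups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .errors import DegenerateInputError, InvalidParameterError, MissingWeightError

logger = logging.getLogger(__name__)

__all__ = [
    "SizeClass",
    "RegionClass",
    "DEFAULT_CHANNEL_WEIGHTS",
    "DEFAULT_REGION_WEIGHTS",
    "WeightConfig",
    "consumption_weights",
    "hazard_weight",
    "channel_weight",
    "classify_region",
    "region_weight",
]


class SizeClass(str, Enum):
    LARGE = "large"
    MEDIUM = "medium"
    SMALL = "small"


class RegionClass(str, Enum):
    LOCAL_CITY = "local_city"
    LOCAL_REGION = "local_region"
    OTHER_REGION = "other_region"


#: Expert-elicited sales-channel weights by size class.
DEFAULT_CHANNEL_WEIGHTS: dict[SizeClass, float] = {
    SizeClass.LARGE: 1.0,
    SizeClass.MEDIUM: 1.4,
    SizeClass.SMALL: 1.1,
}

#: Expert-elicited production-region weights by region class.
DEFAULT_REGION_WEIGHTS: dict[RegionClass, float] = {
    RegionClass.LOCAL_CITY: 1.0,
    RegionClass.LOCAL_REGION: 0.8,
    RegionClass.OTHER_REGION: 0.7,
}


def consumption_weights(per_capita: Mapping[str, float]) -> dict[str, float]:
    """Normalize per-capita consumption quantities into proportions.

    ``weight_i = n_i / sum(n_k)``; the result sums to 1.

    Raises
    ------
    DegenerateInputError
        If the table is empty, totals zero, or holds a negative entry.
    """
    if not per_capita:
        raise DegenerateInputError("empty consumption table")
    if any(v < 0 for v in per_capita.values()):
        raise DegenerateInputError("negative per-capita consumption")
    total = float(sum(per_capita.values()))
    if total <= 0:
        raise DegenerateInputError("all-zero consumption table")
    return {cat: float(v) / total for cat, v in per_capita.items()}


@dataclass
class WeightConfig:
    """Validated bundle of the four non-factor weights.

    Parameters
    ----------
    consumption_weights
        Category -> proportion in (0, 1]; must sum to 1 within 1e-12.
    hazard_scores
        Project id -> integer hazard score in {1..5}.
    channel_size_map
        Channel name -> size class.
    channel_weights, region_weights
        Size/region class -> positive weight; expert-elicited defaults.
    region_parents
        Region label -> parent-region label, used to decide whether a
        production region lies inside the home region.
    permissive
        When True, unknown projects fall back to hazard score 1 with a
        warning instead of raising.
    normalize_hazard
        When True, hazard scores are divided by 5 so the weight lies in
        (0, 1]. Off by default: the raw 1-5 score enters the product.
    """

    consumption_weights: dict[str, float]
    hazard_scores: dict[str, int]
    channel_size_map: dict[str, SizeClass]
    channel_weights: dict[SizeClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_WEIGHTS)
    )
    region_weights: dict[RegionClass, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    region_parents: dict[str, str] = field(default_factory=dict)
    permissive: bool = False
    normalize_hazard: bool = False

    def __post_init__(self) -> None:
        if not self.consumption_weights:
            raise InvalidParameterError("no consumption weights configured")
        total = sum(self.consumption_weights.values())
        if abs(total - 1.0) > 1e-12:
            raise InvalidParameterError(
                f"consumption weights sum to {total!r}, expected 1"
            )
        if any(w <= 0 for w in self.consumption_weights.values()):
            raise InvalidParameterError("consumption weights must be positive")
        for pid, s in self.hazard_scores.items():
            if s not in (1, 2, 3, 4, 5):
                raise InvalidParameterError(
                    f"hazard score for {pid!r} is {s!r}, expected integer 1-5"
                )
        self.channel_size_map = {
            name: SizeClass(size) for name, size in self.channel_size_map.items()
        }
        self.channel_weights = {
            SizeClass(k): float(v) for k, v in self.channel_weights.items()
        }
        self.region_weights = {
            RegionClass(k): float(v) for k, v in self.region_weights.items()
        }
        for table in (self.channel_weights, self.region_weights):
            if any(v <= 0 for v in table.values()):
                raise InvalidParameterError("all weights must be positive")


def hazard_weight(project_id: str, config: WeightConfig) -> float:
    """Look up the hazard weight for a test project.

    Unknown projects raise unless ``config.permissive`` is set, in which
    case the lowest score (1) is used and a warning emitted.
    """
    score = config.hazard_scores.get(project_id)
    if score is None:
        if not config.permissive:
            raise MissingWeightError(f"no hazard score for project {project_id!r}")
        warnings.warn(
            f"project {project_id!r} missing from hazard table; using score 1",
            stacklevel=2,
        )
        score = 1
    return score / 5.0 if config.normalize_hazard else float(score)


def channel_weight(channel_name: str, config: WeightConfig) -> float:
    """Look up the sales-channel weight via the channel's size class."""
    size = config.channel_size_map.get(channel_name)
    if size is None:
        raise MissingWeightError(f"channel {channel_name!r} has no size class")
    return config.channel_weights[size]


def classify_region(
    production_region: str,
    sampled_city: str,
    home_region: str,
    config: WeightConfig,
) -> RegionClass:
    """Classify where a food was produced relative to the sampling site.

    ``local_city`` when produced in the sampled city itself; ``local_region``
    when the production region's parent (per ``config.region_parents``) is
    the home region, or the label names the home region directly;
    ``other_region`` otherwise.  Total on all string inputs.
    """
    if production_region == sampled_city:
        return RegionClass.LOCAL_CITY
    parent = config.region_parents.get(production_region)
    if parent == home_region or production_region == home_region:
        return RegionClass.LOCAL_REGION
    return RegionClass.OTHER_REGION


def region_weight(
    production_region: str,
    sampled_city: str,
    home_region: str,
    config: WeightConfig,
) -> float:
    """Look up the production-region weight for one record."""
    cls = classify_region(production_region, sampled_city, home_region, config)
    return config.region_weights[cls]
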