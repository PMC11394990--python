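"""Seeded generator for synthetic sampling-and-inspection campaigns.

Emulates the structure of a provincial inspection database — cities, 8 food
categories, a channel catalogue with size classes, per-project permissible
limits, and ~25 mixed auxiliary variables — with a controllable
contamination rate, so the whole pipeline is testable without real data.

Safe results are drawn inside the permissible region (so their score is
strictly positive); contaminated results exceed the relevant bound by a
multiplicative severity draw (so their score is exactly zero).  Auxiliary
variables can carry a planted one-factor structure driven by a latent
city/category signal, or be pure independent noise.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "DEFAULT_CATEGORIES",
    "DEFAULT_CHANNELS",
    "AuxiliarySpec",
    "CampaignConfig",
    "Campaign",
    "generate_weight_tables",
    "generate_campaign",
]

#: Eight top-level food categories (stand-ins, not a real inventory).
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "dairy",
    "starch",
    "grain",
    "meat",
    "soy",
    "produce",
    "edible_oil",
    "catering",
)

#: Sixteen sales channels with their size classes.
DEFAULT_CHANNELS: dict[str, str] = {
    "hypermarket": "large",
    "supermarket": "large",
    "shopping_mall": "large",
    "wholesale_market": "large",
    "chain_store": "medium",
    "vegetable_market": "medium",
    "specialty_store": "medium",
    "farm_market": "medium",
    "online_platform": "medium",
    "restaurant": "medium",
    "grocery": "small",
    "street_vendor": "small",
    "canteen": "small",
    "bakery": "small",
    "butcher_shop": "small",
    "convenience_store": "small",
}

_LIMIT_KINDS = ("max_only", "band", "point", "exact_zero")
_LIMIT_PROBS = (0.70, 0.15, 0.05, 0.10)


@dataclass(frozen=True)
class AuxiliarySpec:
    """Shape of the auxiliary mixed variables attached to each record.

    With the defaults (14 quantitative + 9 qualitative) plus the sampled
    city and channel included downstream, 25 mixed items enter the factor
    analysis.  ``structure='latent'`` drives every auxiliary variable by one
    latent signal with the given strength; ``'noise'`` makes them all
    independent.
    """

    n_quantitative: int = 14
    n_qualitative: int = 9
    levels: tuple[int, ...] = (2, 3, 4, 5, 3, 2, 4, 3, 2)
    structure: Literal["latent", "noise"] = "latent"
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.n_quantitative < 0 or self.n_qualitative < 0:
            raise ConfigError("auxiliary counts must be non-negative")
        if len(self.levels) < self.n_qualitative:
            raise ConfigError("need a level cardinality per qualitative variable")
        if any(c < 2 for c in self.levels[: self.n_qualitative]):
            raise ConfigError("qualitative variables need at least 2 levels")


@dataclass(frozen=True)
class CampaignConfig:
    n_samples: int = 1000
    n_cities: int = 15
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    n_projects: int = 24
    channels: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNELS))
    contamination_rate: float = 0.1
    severity_scale: float = 0.5
    auxiliary: AuxiliarySpec = field(default_factory=AuxiliarySpec)
    home_region: str = "region-X"
    year: int = 2020
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_cities < 1 or self.n_projects < 1:
            raise ConfigError("counts must be >= 1")
        if not self.categories:
            raise ConfigError("need at least one category")
        if not self.channels:
            raise ConfigError("need at least one channel")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ConfigError("contamination_rate must lie in [0, 1]")
        if self.severity_scale <= 0:
            raise ConfigError("severity_scale must be positive")


@dataclass
class Campaign:
    """A generated records table plus the config tables it resolves against."""

    records: pd.DataFrame
    consumption: pd.DataFrame   # category, per_capita
    hazards: pd.DataFrame       # project_id, score
    channels: pd.DataFrame      # channel_name, size_class
    projects: pd.DataFrame      # project_id, min/max limits, unit
    variable_spec: pd.DataFrame  # variable_name, type, include
    region_parents: pd.DataFrame  # region, parent


def _city_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    return [
        f"city-{letters[i]}" if i < 26 else f"city-{i + 1}" for i in range(n)
    ]


def _project_table(config: CampaignConfig, rng: np.random.Generator) -> pd.DataFrame:
    kinds = rng.choice(len(_LIMIT_KINDS), size=config.n_projects, p=_LIMIT_PROBS)
    base = np.round(10.0 ** rng.uniform(-1, 1, size=config.n_projects), 4)
    frac = rng.uniform(0.1, 0.6, size=config.n_projects)
    units = rng.choice(["mg/kg", "mg/L"], size=config.n_projects, p=[0.8, 0.2])
    rows = []
    for i in range(config.n_projects):
        kind = _LIMIT_KINDS[kinds[i]]
        if kind == "max_only":
            mn, mx = 0.0, base[i]
        elif kind == "band":
            mn, mx = np.round(base[i] * frac[i], 6), base[i]
        elif kind == "point":
            mn = mx = base[i]
        else:  # exact_zero
            mn = mx = 0.0
        rows.append(
            {
                "project_id": f"P{i + 1:03d}",
                "min_limit": mn,
                "max_limit": mx,
                "unit": units[i],
                "limit_kind": kind,
            }
        )
    return pd.DataFrame(rows)


def generate_weight_tables(
    config: CampaignConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the consumption, hazards, channels and projects tables.

    Hazard scores are uniform on {1..5}; per-capita consumption is positive;
    every channel in the catalogue is mapped to a size class.  Reproducible:
    the draw stream depends only on ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    projects = _project_table(config, rng)
    hazards = pd.DataFrame(
        {
            "project_id": projects["project_id"],
            "score": rng.integers(1, 6, size=config.n_projects),
        }
    )
    consumption = pd.DataFrame(
        {
            "category": list(config.categories),
            "per_capita": np.round(
                rng.uniform(5.0, 100.0, size=len(config.categories)), 2
            ),
        }
    )
    channels = pd.DataFrame(
        {
            "channel_name": list(config.channels),
            "size_class": [config.channels[c] for c in config.channels],
        }
    )
    return consumption, hazards, channels, projects


def _auxiliary_columns(
    config: CampaignConfig,
    latent: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Quantitative and qualitative auxiliary columns, optionally structured."""
    spec = config.auxiliary
    n = config.n_samples
    structured = spec.structure == "latent"
    cols: dict[str, np.ndarray] = {}
    for j in range(spec.n_quantitative):
        noise = rng.normal(0.0, 1.0, size=n)
        if structured:
            cols[f"aux_q{j + 1:02d}"] = spec.strength * latent + noise
        else:
            cols[f"aux_q{j + 1:02d}"] = noise
    for j in range(spec.n_qualitative):
        n_levels = spec.levels[j]
        jitter = rng.normal(0.0, 1.0, size=n)
        if structured:
            signal = spec.strength * latent + jitter
            # quantile-bin the noisy signal so level membership tracks the factor
            edges = np.quantile(signal, np.linspace(0, 1, n_levels + 1)[1:-1])
            codes = np.digitize(signal, edges)
        else:
            codes = rng.integers(0, n_levels, size=n)
        cols[f"aux_c{j + 1:02d}"] = np.array(
            [f"L{c + 1}" for c in codes], dtype=object
        )
    return cols


def generate_campaign(config: CampaignConfig) -> Campaign:
    """Generate a full campaign: records plus all resolvable config tables.

    Deterministic under a fixed config (same seed twice gives identical
    tables).  With ``contamination_rate = 0`` every record scores Q > 0;
    contaminated records always score Q = 0.
    """
    consumption, hazards, channels, projects = generate_weight_tables(config)
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_samples
    cities = _city_names(config.n_cities)
    channel_names = list(config.channels)

    city_idx = rng.integers(0, config.n_cities, size=n)
    cat_idx = rng.integers(0, len(config.categories), size=n)
    sub_idx = rng.integers(1, 3, size=n)
    proj_idx = rng.integers(0, config.n_projects, size=n)
    chan_idx = rng.integers(0, len(channel_names), size=n)

    # production region: same city / elsewhere in the home region / outside
    u_region = rng.random(n)
    other_city = rng.integers(0, config.n_cities, size=n)
    ext_label = rng.integers(1, 6, size=n)
    production = np.empty(n, dtype=object)
    for i in range(n):
        if u_region[i] < 0.5:
            production[i] = cities[city_idx[i]]
        elif u_region[i] < 0.8:
            production[i] = cities[other_city[i]]
        else:
            production[i] = f"external-{ext_label[i]}"

    contaminated = rng.random(n) < config.contamination_rate
    severity = rng.exponential(config.severity_scale, size=n)
    u_safe = rng.random(n)

    mn = projects["min_limit"].to_numpy(float)[proj_idx]
    mx = projects["max_limit"].to_numpy(float)[proj_idx]
    kind = projects["limit_kind"].to_numpy(object)[proj_idx]

    T = np.zeros(n)
    is_max = kind == "max_only"
    is_band = kind == "band"
    is_point = kind == "point"
    is_zero = kind == "exact_zero"
    T[is_max] = u_safe[is_max] * mx[is_max]
    T[is_band] = mn[is_band] + u_safe[is_band] * (mx[is_band] - mn[is_band])
    T[is_point] = mn[is_point] * (1.0 + 0.9 * u_safe[is_point])
    T[is_zero] = 0.0
    c = contaminated
    T[c & (is_max | is_band)] = mx[c & (is_max | is_band)] * (
        1.0 + severity[c & (is_max | is_band)]
    )
    T[c & is_point] = 2.0 * mn[c & is_point] * (1.0 + severity[c & is_point])
    T[c & is_zero] = severity[c & is_zero] + 1e-6

    # latent factor: city and category effects plus idiosyncratic noise
    city_eff = rng.normal(0.0, 1.0, size=config.n_cities)
    cat_eff = rng.normal(0.0, 1.0, size=len(config.categories))
    latent = city_eff[city_idx] + cat_eff[cat_idx] + rng.normal(0.0, 0.5, size=n)
    aux = _auxiliary_columns(config, latent, rng)

    cat_arr = np.array(config.categories, dtype=object)[cat_idx]
    records = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:06d}" for i in range(n)],
            "year": config.year,
            "city": np.array(cities, dtype=object)[city_idx],
            "category": cat_arr,
            "subcategory": [f"{c}/sub{s}" for c, s in zip(cat_arr, sub_idx)],
            "project_id": projects["project_id"].to_numpy(object)[proj_idx],
            "test_result": T,
            "min_limit": mn,
            "max_limit": mx,
            "unit": projects["unit"].to_numpy(object)[proj_idx],
            "channel": np.array(channel_names, dtype=object)[chan_idx],
            "production_region": production,
            **aux,
        }
    )

    spec_rows = (
        [("city", "qualitative"), ("channel", "qualitative")]
        + [(f"aux_q{j + 1:02d}", "quantitative") for j in range(config.auxiliary.n_quantitative)]
        + [(f"aux_c{j + 1:02d}", "qualitative") for j in range(config.auxiliary.n_qualitative)]
    )
    variable_spec = pd.DataFrame(spec_rows, columns=["variable_name", "type"])
    variable_spec["include"] = True

    region_parents = pd.DataFrame(
        {"region": cities, "parent": config.home_region}
    )

    return Campaign(
        records=records,
        consumption=consumption,
        hazards=hazards,
        channels=channels,
        projects=projects,
        variable_spec=variable_spec,
        region_parents=region_parents,
    )
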