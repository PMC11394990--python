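"""Readers, writers, run configuration, and the end-to-end pipeline.

The pipeline is: load tables -> score Q -> attach the four table weights ->
factor-analyse the auxiliary variables for the per-sample correction weight
-> comprehensive degrees for both methods -> city and category index
reports -> paired-t comparison per grouping.  Any stage failure is wrapped
in a :class:`~fsindex.errors.StageError` naming the stage.

All outputs are plain CSV/JSON written deterministically (sorted keys, no
timestamps) so identical inputs give byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import ComparisonResult, paired_t
from .errors import ConfigError, FsindexError, MissingWeightError, StageError
from .famd import FadmParams, FactorModel, Retention, encode_mixed, famd_decompose, fadm_weight
from .index import IndexReport, build_report, comprehensive_degree, expert_baseline_degree
from .qualification import score_records
from .weights import RegionClass, SizeClass, WeightConfig, consumption_weights

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineParams",
    "PipelineResult",
    "load_tables",
    "build_weight_config",
    "evaluate_tables",
    "evaluate_campaign",
    "run_pipeline",
    "write_outputs",
    "fixture_dir",
]


def fixture_dir() -> Path:
    """Path to the bundled n=200 synthetic fixture."""
    return Path(resources.files("fsindex") / "data" / "fixture")


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    records: Path
    consumption: Path
    hazards: Path
    channels: Path
    variable_spec: Path
    region_parents: Path | None = None
    home_region: str = "region-X"
    k: float = 100.0
    retention: str = "cumulative:0.8"
    orientation: Literal["increasing", "decreasing"] = "increasing"
    scaling: Literal["minmax", "raw"] = "minmax"
    compare_on: Literal["scaled", "raw"] = "scaled"
    stratum: str | None = None
    permissive: bool = False
    normalize_hazard: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("records", "consumption", "hazards", "channels", "variable_spec"):
            setattr(self, name, Path(getattr(self, name)))
        if self.region_parents is not None:
            self.region_parents = Path(self.region_parents)
        for name in ("records", "consumption", "hazards", "channels", "variable_spec"):
            if not getattr(self, name).is_file():
                raise ConfigError(f"{name} file not found: {getattr(self, name)}")
        if self.region_parents is not None and not self.region_parents.is_file():
            raise ConfigError(f"region_parents file not found: {self.region_parents}")
        self.fadm_params  # validate k/retention/orientation eagerly

    @property
    def fadm_params(self) -> FadmParams:
        return FadmParams(
            k=self.k,
            retention=Retention.parse(self.retention),
            orientation=self.orientation,
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML or JSON run configuration, applying overrides."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent
        for name in ("records", "consumption", "hazards", "channels",
                     "variable_spec", "region_parents"):
            if raw.get(name) is not None and not Path(raw[name]).is_absolute():
                raw[name] = base / raw[name]
        return cls(**raw)

    @classmethod
    def for_fixture(cls, **overrides) -> "RunConfig":
        """Run configuration pointing at the bundled fixture."""
        d = fixture_dir()
        params = dict(
            records=d / "records.csv",
            consumption=d / "consumption.csv",
            hazards=d / "hazards.csv",
            channels=d / "channels.csv",
            variable_spec=d / "variable_spec.csv",
            region_parents=d / "region_parents.csv",
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class PipelineResult:
    scored: pd.DataFrame
    reports: list[IndexReport]
    comparisons: dict[str, ComparisonResult]
    factor_model: FactorModel
    exclusions: list[str]
    config: "RunConfig | PipelineParams"

    def report(self, grouping: str, method: str) -> IndexReport:
        for r in self.reports:
            if r.grouping == grouping and r.method == method:
                return r
        raise KeyError(f"no report for {grouping}/{method}")


def load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    tables = {
        "records": pd.read_csv(config.records),
        "consumption": pd.read_csv(config.consumption),
        "hazards": pd.read_csv(config.hazards),
        "channels": pd.read_csv(config.channels),
        "variable_spec": pd.read_csv(config.variable_spec),
    }
    if config.region_parents is not None:
        tables["region_parents"] = pd.read_csv(config.region_parents)
    else:
        tables["region_parents"] = pd.DataFrame(columns=["region", "parent"])
    return tables


def build_weight_config(
    tables: dict[str, pd.DataFrame], config: RunConfig
) -> WeightConfig:
    cons = tables["consumption"]
    haz = tables["hazards"]
    chan = tables["channels"]
    parents = tables["region_parents"]
    return WeightConfig(
        consumption_weights=consumption_weights(
            dict(zip(cons["category"].astype(str), cons["per_capita"].astype(float)))
        ),
        hazard_scores=dict(
            zip(haz["project_id"].astype(str), haz["score"].astype(int))
        ),
        channel_size_map=dict(
            zip(chan["channel_name"].astype(str), chan["size_class"].astype(str))
        ),
        region_parents=dict(
            zip(parents["region"].astype(str), parents["parent"].astype(str))
        ),
        permissive=config.permissive,
        normalize_hazard=config.normalize_hazard,
    )


def _attach_weights(
    df: pd.DataFrame, wcfg: WeightConfig, config: RunConfig
) -> pd.DataFrame:
    """Vectorized lookup of the four table weights; raises on unresolved rows."""
    df = df.copy()

    wc = df["category"].astype(str).map(wcfg.consumption_weights)
    if wc.isna().any():
        missing = sorted(df.loc[wc.isna(), "category"].astype(str).unique())
        raise MissingWeightError(f"no consumption weight for categories {missing}")
    df["w_consumption"] = wc.astype(float)

    scores = df["project_id"].astype(str).map(wcfg.hazard_scores)
    if scores.isna().any():
        missing = sorted(df.loc[scores.isna(), "project_id"].astype(str).unique())
        if not wcfg.permissive:
            raise MissingWeightError(f"no hazard score for projects {missing}")
        logger.warning("projects %s missing hazard scores; using score 1", missing)
        scores = scores.fillna(1)
    wh = scores.astype(float)
    df["w_hazard"] = wh / 5.0 if wcfg.normalize_hazard else wh

    sizes = df["channel"].astype(str).map(wcfg.channel_size_map)
    if sizes.isna().any():
        missing = sorted(df.loc[sizes.isna(), "channel"].astype(str).unique())
        raise MissingWeightError(f"no size class for channels {missing}")
    df["w_channel"] = sizes.map(wcfg.channel_weights).astype(float)

    prod = df["production_region"].astype(str)
    city = df["city"].astype(str)
    parent = prod.map(wcfg.region_parents)
    region_class = np.where(
        prod.to_numpy() == city.to_numpy(),
        RegionClass.LOCAL_CITY.value,
        np.where(
            (parent == config.home_region) | (prod == config.home_region),
            RegionClass.LOCAL_REGION.value,
            RegionClass.OTHER_REGION.value,
        ),
    )
    df["region_class"] = region_class
    df["w_region"] = (
        pd.Series(region_class, index=df.index)
        .map(lambda c: wcfg.region_weights[RegionClass(c)])
        .astype(float)
    )
    return df


@dataclass
class PipelineParams:
    """Non-path pipeline parameters, for running on in-memory tables."""

    home_region: str = "region-X"
    k: float = 100.0
    retention: str = "cumulative:0.8"
    orientation: Literal["increasing", "decreasing"] = "increasing"
    scaling: Literal["minmax", "raw"] = "minmax"
    compare_on: Literal["scaled", "raw"] = "scaled"
    stratum: str | None = None
    permissive: bool = False
    normalize_hazard: bool = False

    @property
    def fadm_params(self) -> FadmParams:
        return FadmParams(
            k=self.k,
            retention=Retention.parse(self.retention),
            orientation=self.orientation,
        )


def evaluate_tables(
    tables: dict[str, pd.DataFrame], params: PipelineParams | None = None
) -> PipelineResult:
    """Run the pipeline on pre-loaded tables (no file IO).

    ``tables`` must hold records, consumption, hazards, channels,
    variable_spec and (optionally) region_parents frames with the same
    columns as their CSV counterparts.
    """
    params = params or PipelineParams()
    tables = dict(tables)
    if "region_parents" not in tables:
        tables["region_parents"] = pd.DataFrame(columns=["region", "parent"])
    return _run_stages(tables, params)


def evaluate_campaign(campaign, params: PipelineParams | None = None) -> PipelineResult:
    """Run the pipeline directly on a synthetic :class:`~fsindex.synthetic.Campaign`."""
    return evaluate_tables(
        {
            "records": campaign.records,
            "consumption": campaign.consumption,
            "hazards": campaign.hazards,
            "channels": campaign.channels,
            "variable_spec": campaign.variable_spec,
            "region_parents": campaign.region_parents,
        },
        params,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full evaluation pipeline from files; stage failures are tagged."""
    try:
        tables = load_tables(config)
    except Exception as exc:
        raise StageError("load", exc) from exc
    params = PipelineParams(
        home_region=config.home_region,
        k=config.k,
        retention=config.retention,
        orientation=config.orientation,
        scaling=config.scaling,
        compare_on=config.compare_on,
        stratum=config.stratum,
        permissive=config.permissive,
        normalize_hazard=config.normalize_hazard,
    )
    result = _run_stages(tables, params)
    result.config = config
    return result


def _run_stages(tables: dict[str, pd.DataFrame], config: PipelineParams) -> PipelineResult:
    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("load"):
        wcfg = build_weight_config(tables, config)

    with stage("qualification"):
        scored, exclusions = score_records(tables["records"])
        if scored.empty:
            raise FsindexError("no scoreable records after exclusions")

    with stage("weights"):
        scored = _attach_weights(scored, wcfg, config)

    with stage("famd"):
        spec = tables["variable_spec"]
        if "include" in spec.columns:
            spec = spec[spec["include"].astype(bool)]
        quant = [str(v) for v in spec.loc[spec["type"] == "quantitative", "variable_name"]]
        qual = [str(v) for v in spec.loc[spec["type"] == "qualitative", "variable_name"]]
        design = encode_mixed(scored, quant, qual)
        model = famd_decompose(design, config.fadm_params)
        scored["w_fadm"] = fadm_weight(model, config.fadm_params)

    with stage("index"):
        scored["q_bar_fadm"] = comprehensive_degree(
            scored["Q"].to_numpy(),
            scored["w_consumption"].to_numpy(),
            scored["w_hazard"].to_numpy(),
            scored["w_channel"].to_numpy(),
            scored["w_region"].to_numpy(),
            scored["w_fadm"].to_numpy(),
        )
        scored["q_bar_expert"] = expert_baseline_degree(
            scored["Q"].to_numpy(),
            scored["w_consumption"].to_numpy(),
            scored["w_hazard"].to_numpy(),
            scored["w_channel"].to_numpy(),
            scored["w_region"].to_numpy(),
        )
        reports = []
        for grouping in ("city", "category"):
            for method, col in (("fadm", "q_bar_fadm"), ("expert", "q_bar_expert")):
                reports.append(
                    build_report(
                        scored[col].to_numpy(),
                        scored[grouping],
                        method=method,
                        grouping=grouping,
                        scaling=config.scaling,
                        stratum=config.stratum,
                    )
                )

    with stage("compare"):
        comparisons: dict[str, ComparisonResult] = {}
        for grouping in ("city", "category"):
            fadm = next(r for r in reports if r.grouping == grouping and r.method == "fadm")
            expert = next(r for r in reports if r.grouping == grouping and r.method == "expert")
            units = sorted(fadm.per_unit_raw)
            if config.compare_on == "scaled":
                x = [fadm.per_unit_index[u] for u in units]
                y = [expert.per_unit_index[u] for u in units]
            else:
                x = [fadm.per_unit_raw[u] for u in units]
                y = [expert.per_unit_raw[u] for u in units]
            comparisons[grouping] = paired_t(x, y)

    return PipelineResult(scored, reports, comparisons, model, exclusions, config)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def famd_summary(model: FactorModel) -> dict:
    return {
        "lambda1_quantitative": model.lambda1_quant,
        "lambda1_qualitative": model.lambda1_qual,
        "singular_values": [float(s) for s in model.singular_values],
        "variance_contributions": [float(w) for w in model.variance_contributions],
        "n_retained": model.n_retained,
        "n_samples": model.n,
    }


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    """Write scored.csv, indexes.csv, comparison.json, famd_summary.json,
    exclusions.log and manifest.json under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    result.scored.to_csv(out / "scored.csv", index=False)
    pd.concat([r.to_frame() for r in result.reports], ignore_index=True).to_csv(
        out / "indexes.csv", index=False
    )
    _json_dump(
        {g: c.to_dict() for g, c in result.comparisons.items()},
        out / "comparison.json",
    )
    _json_dump(famd_summary(result.factor_model), out / "famd_summary.json")
    (out / "exclusions.log").write_text(
        "".join(line + "\n" for line in result.exclusions)
    )

    inputs: dict[str, Path] = {}
    if isinstance(cfg, RunConfig):
        inputs = {
            "records": cfg.records,
            "consumption": cfg.consumption,
            "hazards": cfg.hazards,
            "channels": cfg.channels,
            "variable_spec": cfg.variable_spec,
        }
        if cfg.region_parents is not None:
            inputs["region_parents"] = cfg.region_parents
    manifest = {
        "version": __version__,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()
        },
        "parameters": {
            "home_region": cfg.home_region,
            "k": cfg.k,
            "retention": cfg.retention,
            "orientation": cfg.orientation,
            "scaling": cfg.scaling,
            "compare_on": cfg.compare_on,
            "stratum": cfg.stratum,
            "permissive": cfg.permissive,
            "normalize_hazard": cfg.normalize_hazard,
            "seed": getattr(cfg, "seed", None),
        },
        "n_scored": int(len(result.scored)),
        "n_excluded": len(result.exclusions),
    }
    _json_dump(manifest, out / "manifest.json")
    return out
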