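"""Run configuration: schema, YAML load/save, computed-support resolution.

A run config defines the indicator tree (dimension -> factor -> indicator
with pressure/support values and units), the warning-zone width, and the
parameters of the raw-data estimators (suitability weights and thresholds,
LAI-table overrides, pollutant combine rule).  An indicator may declare
``computed_by`` instead of a literal ``support`` value, naming one of the
package's estimators together with the data files it needs; the support end
is then computed from raw data at assessment time.

Validation is schema-first: unknown keys are rejected with their location
and all violations are reported at once, not just the first.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as PydanticValidationError

from . import ecosystem, suitability, water
from .assessment import (
    AggregationMode,
    AssessmentTree,
    Dimension,
    Factor,
    IndicatorPair,
)
from .capacity import LoadBounds, QualityStandard, ResponseField, solve_capacity
from .errors import ConfigError

ESTIMATORS = (
    "suitable_area",
    "available_water",
    "assimilative_capacity",
    "sum_lai",
    "hard_coral_coverage",
    "fish_density",
)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayerRef(_Model):
    path: str
    name: str
    weight: float


class ComputedBy(_Model):
    """Reference from an indicator to a raw-data support estimator."""

    estimator: Literal[
        "suitable_area",
        "available_water",
        "assimilative_capacity",
        "sum_lai",
        "hard_coral_coverage",
        "fish_density",
    ]
    # estimator-specific inputs; paths are relative to the config file
    layers: Optional[list["LayerRef"]] = None  # suitable_area
    components: Optional[dict[str, float]] = None  # available_water
    components_csv: Optional[str] = None  # available_water
    response_csv: Optional[str] = None  # assimilative_capacity
    standards_csv: Optional[str] = None  # assimilative_capacity
    bounds_csv: Optional[str] = None  # assimilative_capacity
    composition_csv: Optional[str] = None  # sum_lai
    transects_csv: Optional[str] = None  # coverage / density
    scale: float = 1.0  # unit conversion applied to the estimate


class IndicatorConfig(_Model):
    id: str
    name: str = ""
    units: str = ""
    pressure: float
    support: Optional[float] = None
    weight: float = 1.0
    computed_by: Optional[ComputedBy] = None


class FactorConfig(_Model):
    id: str
    name: str = ""
    indicators: list[IndicatorConfig] = Field(min_length=1)


class DimensionConfig(_Model):
    id: str
    name: str = ""
    aggregation_mode: Literal["flat", "nested"] = "flat"
    factors: list[FactorConfig] = Field(min_length=1)


class SuitabilityConfig(_Model):
    thresholds: tuple[float, float] = suitability.DEFAULT_THRESHOLDS


class RunConfig(_Model):
    """Top-level schema for one assessment run."""

    name: str = ""
    warning_width: float = Field(default=0.10, ge=0.0, lt=1.0)
    dimensions: list[DimensionConfig] = Field(min_length=1)
    suitability: SuitabilityConfig = SuitabilityConfig()
    lai_table: Optional[dict[str, float]] = None
    pollutant_combine: Literal["min", "rms"] = "min"
    output_dir: str = "."
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run config.

    Raises :class:`ConfigError` listing every violation with its location.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping at top level")
    try:
        cfg = RunConfig.model_validate(raw)
    except PydanticValidationError as exc:
        violations = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"{path}: {len(violations)} config violation(s):\n  "
            + "\n  ".join(violations),
            violations=violations,
        ) from exc
    _check_supports(cfg)
    return cfg


def _check_supports(cfg: RunConfig) -> None:
    problems = []
    for dim in cfg.dimensions:
        for fac in dim.factors:
            for ind in fac.indicators:
                if ind.support is None and ind.computed_by is None:
                    problems.append(
                        f"dimensions.{dim.id}.{fac.id}.{ind.id}: "
                        "needs either 'support' or 'computed_by'"
                    )
    if problems:
        raise ConfigError(
            f"{len(problems)} config violation(s):\n  " + "\n  ".join(problems),
            violations=problems,
        )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML; load_config round-trips it identically."""
    data = cfg.model_dump(exclude_none=True)
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Estimator resolution and tree construction
# ---------------------------------------------------------------------------


def _resolve_support(cb: ComputedBy, cfg: RunConfig, base: Path) -> float:
    est = cb.estimator
    if est == "suitable_area":
        if not cb.layers:
            raise ConfigError("suitable_area needs 'layers'")
        layers = [
            suitability.read_factor_layer(base / l.path, l.name, l.weight)
            for l in cb.layers
        ]
        grid = suitability.score_cells(layers)
        suitability.classify_suitability(grid, cfg.suitability.thresholds)
        return suitability.suitable_area(grid) * cb.scale
    if est == "available_water":
        comps = dict(cb.components or {})
        if cb.components_csv:
            df = pd.read_csv(base / cb.components_csv)
            comps.update(dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float))))
        if not comps:
            raise ConfigError("available_water needs 'components' or 'components_csv'")
        return water.available_water(water.WaterBudget(components=comps)) * cb.scale
    if est == "assimilative_capacity":
        if not (cb.response_csv and cb.standards_csv and cb.bounds_csv):
            raise ConfigError(
                "assimilative_capacity needs response_csv, standards_csv and bounds_csv"
            )
        fld = read_response_field(base / cb.response_csv)
        std = read_standards(base / cb.standards_csv)
        bnd = read_bounds(base / cb.bounds_csv)
        return solve_capacity(fld, std, bnd).capacity * cb.scale
    if est == "sum_lai":
        if not cb.composition_csv:
            raise ConfigError("sum_lai needs 'composition_csv'")
        comp = read_composition(base / cb.composition_csv)
        return ecosystem.sum_lai(comp, cfg.lai_table) * cb.scale
    if est == "hard_coral_coverage":
        if not cb.transects_csv:
            raise ConfigError("hard_coral_coverage needs 'transects_csv'")
        ts = read_point_intercepts(base / cb.transects_csv)
        return (
            ecosystem.pool_transects([ecosystem.hard_coral_coverage(t) for t in ts])
            * cb.scale
        )
    if est == "fish_density":
        if not cb.transects_csv:
            raise ConfigError("fish_density needs 'transects_csv'")
        ts = read_belts(base / cb.transects_csv)
        return (
            ecosystem.pool_transects([ecosystem.fish_density(t) for t in ts]) * cb.scale
        )
    raise ConfigError(f"unknown estimator {est!r}")  # pragma: no cover


def build_tree(cfg: RunConfig, base_dir: str | Path = ".") -> AssessmentTree:
    """Materialize the assessment tree, resolving computed_by supports."""
    base = Path(base_dir)
    dims = []
    for dc in cfg.dimensions:
        factors = []
        for fc in dc.factors:
            inds = []
            for ic in fc.indicators:
                support = ic.support
                if ic.computed_by is not None:
                    support = _resolve_support(ic.computed_by, cfg, base)
                inds.append(
                    IndicatorPair(
                        id=ic.id,
                        name=ic.name or ic.id,
                        pressure=ic.pressure,
                        support=float(support),
                        units=ic.units,
                        weight=ic.weight,
                    )
                )
            factors.append(Factor(id=fc.id, name=fc.name or fc.id, indicators=inds))
        dims.append(
            Dimension(
                id=dc.id,
                name=dc.name or dc.id,
                aggregation_mode=AggregationMode(dc.aggregation_mode),
                factors=factors,
            )
        )
    return AssessmentTree(dimensions=dims, name=cfg.name)


# ---------------------------------------------------------------------------
# CSV readers (RFC 4180 via pandas)
# ---------------------------------------------------------------------------


def read_response_field(path: str | Path) -> ResponseField:
    """Response-field CSV: areas as rows (first column = area id), sources
    as columns; an optional 'pollutant' stem is taken from the file name."""
    df = pd.read_csv(path, index_col=0)
    return ResponseField(
        matrix=df.to_numpy(dtype=float),
        area_ids=[str(i) for i in df.index],
        source_ids=[str(c) for c in df.columns],
        pollutant=Path(path).stem,
    )


def read_standards(path: str | Path) -> QualityStandard:
    """Standards CSV: columns area, limit [, background]."""
    df = pd.read_csv(path)
    bg = df["background"].to_numpy(float) if "background" in df.columns else None
    return QualityStandard(limits=df["limit"].to_numpy(float), background=bg)


def read_bounds(path: str | Path) -> LoadBounds:
    """Bounds CSV: columns source, lower, upper."""
    df = pd.read_csv(path)
    return LoadBounds(
        lower=df["lower"].to_numpy(float), upper=df["upper"].to_numpy(float)
    )


def read_composition(path: str | Path) -> ecosystem.LandCoverComposition:
    """Land-cover CSV: columns type, area."""
    df = pd.read_csv(path)
    return ecosystem.LandCoverComposition(
        areas=dict(zip(df["type"], df["area"].astype(float)))
    )


def read_point_intercepts(path: str | Path) -> list[ecosystem.PointInterceptTransect]:
    """Point-intercept CSV: columns id, n, M."""
    df = pd.read_csv(path)
    return [
        ecosystem.PointInterceptTransect(id=str(r.id), n=int(r.n), M=int(r.M))
        for r in df.itertuples(index=False)
    ]


def read_belts(path: str | Path) -> list[ecosystem.BeltTransect]:
    """Belt-transect CSV: columns id, N, L, W."""
    df = pd.read_csv(path)
    return [
        ecosystem.BeltTransect(id=str(r.id), N=int(r.N), L=float(r.L), W=float(r.W))
        for r in df.itertuples(index=False)
    ]


def write_point_intercepts(
    transects: list[ecosystem.PointInterceptTransect], path: str | Path
) -> None:
    pd.DataFrame(
        [{"id": t.id, "n": t.n, "M": t.M} for t in transects]
    ).to_csv(path, index=False)


def write_belts(transects: list[ecosystem.BeltTransect], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": t.id, "N": t.N, "L": t.L, "W": t.W} for t in transects]
    ).to_csv(path, index=False)


def write_composition(comp: ecosystem.LandCoverComposition, path: str | Path) -> None:
    pd.DataFrame(
        [{"type": t, "area": a} for t, a in comp.areas.items()]
    ).to_csv(path, index=False)


def write_response_field(fld: ResponseField, path: str | Path) -> None:
    pd.DataFrame(
        fld.matrix, index=fld.area_ids, columns=fld.source_ids
    ).to_csv(path)
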