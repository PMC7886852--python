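"""Pressure-support indicator tree and vector surplus-ratio aggregation.

Carrying capacity is assessed by comparing, for every indicator, the
pressure exerted by human activity (p) with the support the island system
can provide (s, in the same units).  The per-indicator surplus ratio

    d = (s - p) / s = 1 - p / s

is positive when support exceeds pressure (surplus), zero at full load and
negative when the indicator is over-loaded.  Ratios are combined up the
tree (indicators -> core factors -> dimensions -> overall index) by the
vector-modulus rule

    D = 1 - sqrt( (1/n) * sum_j (1 - d_j)^2 ),

i.e. one minus the root-mean-square of the per-child load factors
(1 - d_j), with equal weights at every level.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Sequence

from .errors import ConfigError, StructuralError, ValidationError

DEFAULT_WARNING_WIDTH = 0.10


class CarryingState(str, enum.Enum):
    """Qualitative carrying state derived from a surplus ratio."""

    OVER_LOADED = "over-loaded"
    FULL_LOADED = "full-loaded"
    WARNING = "warning"
    SURPLUS = "surplus"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class AggregationMode(str, enum.Enum):
    """How a dimension pools its indicators.

    ``flat`` applies the vector rule once over all indicators of the
    dimension; ``nested`` first pools each core factor's indicators, then
    pools the factor ratios.
    """

    FLAT = "flat"
    NESTED = "nested"


# ---------------------------------------------------------------------------
# Tree node types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndicatorPair:
    """One matched pressure/support pair.

    The support value is the threshold for the pressure value; both carry
    the same units tag (e.g. km^2 for land, t/a for water consumption).
    """

    id: str
    name: str
    pressure: float
    support: float
    units: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.support > 0):
            raise ValidationError(
                f"indicator {self.id!r}: support must be positive, got {self.support}"
            )
        if self.pressure < 0:
            raise ValidationError(
                f"indicator {self.id!r}: pressure must be non-negative, got {self.pressure}"
            )

    @property
    def surplus_ratio(self) -> float:
        return compute_surplus_ratio(self.pressure, self.support, indicator=self.id)


@dataclass(frozen=True)
class SurplusResult:
    """A surplus ratio with its classified state and degree in percent."""

    d: float
    state: CarryingState
    degree: float

    @classmethod
    def from_ratio(cls, d: float, warning_width: float = DEFAULT_WARNING_WIDTH) -> "SurplusResult":
        return cls(d=d, state=classify_state(d, warning_width), degree=abs(d) * 100.0)


@dataclass
class Factor:
    """A core factor: a named group of indicators within a dimension."""

    id: str
    name: str
    indicators: list[IndicatorPair] = field(default_factory=list)


@dataclass
class Dimension:
    """One of the four assessment dimensions (resources supply, environmental
    assimilation, ecosystem services, socio-economic supporting)."""

    id: str
    name: str
    factors: list[Factor] = field(default_factory=list)
    aggregation_mode: AggregationMode = AggregationMode.FLAT

    def indicators(self) -> list[IndicatorPair]:
        return [ind for f in self.factors for ind in f.indicators]


@dataclass
class AssessmentTree:
    """The full indicator hierarchy for one island and year."""

    dimensions: list[Dimension] = field(default_factory=list)
    name: str = ""

    def validate(self) -> None:
        if not self.dimensions:
            raise StructuralError("assessment tree has no dimensions")
        seen: set[str] = set()
        for dim in self.dimensions:
            if not dim.factors:
                raise StructuralError(f"dimension {dim.id!r} has no factors")
            for fac in dim.factors:
                if not fac.indicators:
                    raise StructuralError(
                        f"factor {dim.id!r}/{fac.id!r} has no indicators"
                    )
                for ind in fac.indicators:
                    if ind.id in seen:
                        raise StructuralError(
                            f"indicator id {ind.id!r} appears more than once"
                        )
                    seen.add(ind.id)


@dataclass(frozen=True)
class ReportNode:
    """One row of an assessment report: a tree node with its result."""

    path: str  # e.g. "ecosystem/coral_reef/hcc"
    name: str
    level: str  # "indicator" | "factor" | "dimension" | "overall"
    result: SurplusResult


@dataclass
class AssessmentReport:
    """Surplus ratios and states at every level of the tree.

    Every value is recomputable from the tree's (p, s) pairs alone; the
    report stores full precision and leaves display rounding to renderers.
    """

    nodes: list[ReportNode]
    warning_width: float
    source: str = ""
    timestamp: str = ""

    @property
    def overall(self) -> SurplusResult:
        return next(n.result for n in self.nodes if n.level == "overall")

    def dimension_results(self) -> dict[str, SurplusResult]:
        return {n.path: n.result for n in self.nodes if n.level == "dimension"}

    def indicator_results(self) -> dict[str, SurplusResult]:
        return {n.path: n.result for n in self.nodes if n.level == "indicator"}


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def compute_surplus_ratio(
    pressure: float, support: float, indicator: str | None = None
) -> float:
    """Surplus ratio d = 1 - pressure/support = (support - pressure)/support.

    d > 0 iff pressure < support (surplus); d = 0 at full load; d < 0 when
    over-loaded.  Always d <= 1 since pressure >= 0 and support > 0.
    """
    if not (support > 0) or not math.isfinite(support):
        who = f" for indicator {indicator!r}" if indicator else ""
        raise ValidationError(f"support must be positive and finite{who}, got {support}")
    if pressure < 0:
        who = f" for indicator {indicator!r}" if indicator else ""
        raise ValidationError(f"pressure must be non-negative{who}, got {pressure}")
    return 1.0 - pressure / support


def classify_state(
    d: float, warning_width: float = DEFAULT_WARNING_WIDTH
) -> CarryingState:
    """Classify a surplus ratio into a carrying state.

    A positive ratio smaller than ``warning_width`` is flagged as a warning:
    nominally in surplus but within the uncertainty buffer of the full-load
    critical point.  With ``warning_width = 0`` the warning state is
    unreachable.  d = 0 exactly is full-loaded, never warning.
    """
    if not (0.0 <= warning_width < 1.0):
        raise ConfigError(
            f"warning_width must lie in [0, 1), got {warning_width}"
        )
    if d > 1.0:
        raise ValidationError(f"surplus ratio cannot exceed 1, got {d}")
    if d < 0:
        return CarryingState.OVER_LOADED
    if d == 0:
        return CarryingState.FULL_LOADED
    if d < warning_width:
        return CarryingState.WARNING
    return CarryingState.SURPLUS


def aggregate(children: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Combine child surplus ratios into one: 1 - RMS of the load factors.

    D = 1 - sqrt( sum_j w_j (1 - d_j)^2 / sum_j w_j ), equal weights by
    default.  Permutation invariant; a singleton aggregates to itself; the
    result never exceeds the largest child.
    """
    ratios = list(children)
    if not ratios:
        raise StructuralError("cannot aggregate an empty list of surplus ratios")
    for d in ratios:
        if d > 1.0:
            raise ValidationError(f"surplus ratio cannot exceed 1, got {d}")
    if weights is None:
        w = [1.0] * len(ratios)
    else:
        w = list(weights)
        if len(w) != len(ratios):
            raise StructuralError("weights and children differ in length")
        if any(x <= 0 for x in w):
            raise ValidationError("aggregation weights must be positive")
    total = sum(w)
    mean_sq = sum(wi * (1.0 - d) ** 2 for wi, d in zip(w, ratios)) / total
    return 1.0 - math.sqrt(mean_sq)


def aggregate_overall(dimension_ratios: Sequence[float]) -> float:
    """Combine dimension ratios into the overall index.

    The formula is identical to :func:`aggregate`; the separate name keeps
    reports explicit about the level at which pooling happened.
    """
    return aggregate(dimension_ratios)


def assess_tree(
    tree: AssessmentTree,
    warning_width: float = DEFAULT_WARNING_WIDTH,
    source: str = "",
) -> AssessmentReport:
    """Assess a full tree: per-indicator ratios, factor/dimension pooling
    (flat or nested per dimension), then the overall index.

    Flat dimensions pool all their indicators in one step; nested dimensions
    pool each factor's indicators first, then the factor ratios.  Factor
    rows appear in the report only for nested dimensions, where they are a
    genuine aggregation level.
    """
    tree.validate()
    # validate width before any computation
    classify_state(0.0, warning_width)
    nodes: list[ReportNode] = []
    dim_ratios: list[float] = []

    for dim in tree.dimensions:
        for fac in dim.factors:
            for ind in fac.indicators:
                try:
                    d = ind.surplus_ratio
                except ValidationError as exc:
                    raise ValidationError(
                        f"{dim.id}/{fac.id}/{ind.id}: {exc}"
                    ) from exc
                nodes.append(
                    ReportNode(
                        path=f"{dim.id}/{fac.id}/{ind.id}",
                        name=ind.name,
                        level="indicator",
                        result=SurplusResult.from_ratio(d, warning_width),
                    )
                )
        if dim.aggregation_mode is AggregationMode.NESTED:
            factor_ratios = []
            for fac in dim.factors:
                try:
                    fr = aggregate(
                        [i.surplus_ratio for i in fac.indicators],
                        [i.weight for i in fac.indicators],
                    )
                except StructuralError as exc:
                    raise StructuralError(f"{dim.id}/{fac.id}: {exc}") from exc
                factor_ratios.append(fr)
                nodes.append(
                    ReportNode(
                        path=f"{dim.id}/{fac.id}",
                        name=fac.name,
                        level="factor",
                        result=SurplusResult.from_ratio(fr, warning_width),
                    )
                )
            D_i = aggregate(factor_ratios)
        else:
            D_i = aggregate(
                [i.surplus_ratio for i in dim.indicators()],
                [i.weight for i in dim.indicators()],
            )
        dim_ratios.append(D_i)
        nodes.append(
            ReportNode(
                path=dim.id,
                name=dim.name,
                level="dimension",
                result=SurplusResult.from_ratio(D_i, warning_width),
            )
        )

    D = aggregate_overall(dim_ratios)
    nodes.append(
        ReportNode(
            path="overall",
            name="CORE-CC",
            level="overall",
            result=SurplusResult.from_ratio(D, warning_width),
        )
    )
    return AssessmentReport(
        nodes=nodes,
        warning_width=warning_width,
        source=source,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
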