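"""Seawater assimilative capacity via load-allocation linear programming.

Following total-maximum-daily-load (TMDL) practice, the assimilative
capacity of the waters around an island is the largest total pollutant
load that still meets the water-quality standard everywhere:

    maximize   AC = sum_j Q_j
    subject to sum_j P[i][j] * Q_j <= C_s[i] - background[i]   for each sea area i
               Q_l[j] <= Q_j <= Q_u[j]                          for each source j

where P is the response field: the concentration increment in sea area i
per unit annual load from point source j, precomputed by a hydrodynamic-
water-quality model and supplied here as a matrix.  The LP is solved per
pollutant (e.g. inorganic nitrogen and phosphorus); per-pollutant surplus
ratios 1 - discharge/AC are combined into the single water-assimilation
indicator, by default taking the most binding (minimum) pollutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linprog

from .assessment import aggregate
from .errors import InfeasibleError, ValidationError

BINDING_TOL = 1e-9


@dataclass
class ResponseField:
    """Unit-load concentration response matrix, sea areas x sources.

    ``matrix[i, j]`` is the concentration increment (mg/L) in sea area i
    per unit load (t/a) from source j; entries are finite and >= 0.
    """

    matrix: np.ndarray
    area_ids: list[str] = field(default_factory=list)
    source_ids: list[str] = field(default_factory=list)
    pollutant: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.size == 0:
            raise ValidationError("response field needs >= 1 area and >= 1 source")
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValidationError("response-field entries must be finite and >= 0")
        n_areas, n_sources = self.matrix.shape
        if not self.area_ids:
            self.area_ids = [f"area{i + 1}" for i in range(n_areas)]
        if not self.source_ids:
            self.source_ids = [f"source{j + 1}" for j in range(n_sources)]
        if len(self.area_ids) != n_areas or len(self.source_ids) != n_sources:
            raise ValidationError("area/source id counts do not match the matrix shape")


@dataclass
class QualityStandard:
    """Per-area concentration limits (mg/L) with optional background."""

    limits: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.limits = np.atleast_1d(np.asarray(self.limits, dtype=float))
        if np.any(self.limits <= 0):
            raise ValidationError("quality-standard limits must be positive")
        if self.background is None:
            self.background = np.zeros_like(self.limits)
        else:
            self.background = np.atleast_1d(np.asarray(self.background, dtype=float))
            if np.any(self.background < 0):
                raise ValidationError("background concentrations must be >= 0")
            if self.background.shape != self.limits.shape:
                raise ValidationError("background and limits differ in length")
            if np.any(self.background >= self.limits):
                raise ValidationError(
                    "background must be below the standard in every area"
                )

    @property
    def headroom(self) -> np.ndarray:
        """Concentration budget available to new loads: C_s - background."""
        return self.limits - self.background


@dataclass
class LoadBounds:
    """Per-source lower and upper annual load limits (t/a)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValidationError("lower and upper bounds differ in length")
        if np.any(self.lower < 0):
            raise ValidationError("lower load bounds must be >= 0")
        if np.any(self.upper < self.lower):
            raise ValidationError("upper load bounds must be >= lower bounds")


@dataclass
class CapacityResult:
    """Optimal per-source loads and total assimilative capacity."""

    loads: np.ndarray
    capacity: float
    status: Literal["optimal", "infeasible"]
    binding: list[str] = field(default_factory=list)
    pollutant: str = ""


def solve_capacity(
    field_: ResponseField, std: QualityStandard, bounds: LoadBounds
) -> CapacityResult:
    """Maximize the total load subject to quality standards and load bounds.

    Returns the optimum loads and total capacity AC.  When optima are
    degenerate only AC is well-defined; the load vector is whichever
    optimal vertex the solver returns.  Raises :class:`InfeasibleError`
    naming the violated sea areas when even the lower bounds break a
    standard.
    """
    P = field_.matrix
    n_areas, n_sources = P.shape
    if std.limits.shape[0] != n_areas:
        raise ValidationError(
            f"standards cover {std.limits.shape[0]} areas but the response field has {n_areas}"
        )
    if bounds.lower.shape[0] != n_sources:
        raise ValidationError(
            f"bounds cover {bounds.lower.shape[0]} sources but the response field has {n_sources}"
        )
    b = std.headroom
    base = P @ bounds.lower
    violated = [field_.area_ids[i] for i in np.nonzero(base > b + BINDING_TOL)[0]]
    if violated:
        raise InfeasibleError(
            "quality standards already violated at the minimum loads in areas: "
            + ", ".join(violated),
            violated_areas=violated,
        )
    res = linprog(
        c=-np.ones(n_sources),
        A_ub=P,
        b_ub=b,
        bounds=list(zip(bounds.lower, bounds.upper)),
        method="highs",
    )
    if not res.success:  # pragma: no cover - guarded by the pre-check above
        raise InfeasibleError(f"LP solver failed: {res.message}")
    Q = res.x
    conc = P @ Q
    scale = np.maximum(np.abs(b), 1.0)
    binding = [
        field_.area_ids[i]
        for i in range(n_areas)
        if conc[i] >= b[i] - BINDING_TOL * scale[i]
    ]
    binding += [
        f"{field_.source_ids[j]}:upper"
        for j in range(n_sources)
        if Q[j] >= bounds.upper[j] - BINDING_TOL * max(abs(bounds.upper[j]), 1.0)
    ]
    return CapacityResult(
        loads=Q,
        capacity=float(Q.sum()),
        status="optimal",
        binding=binding,
        pollutant=field_.pollutant,
    )


def assimilation_surplus(
    results: dict[str, CapacityResult | float],
    discharges: dict[str, float],
    combine: Literal["min", "rms"] = "min",
) -> float:
    """Surplus ratio of the water-assimilation indicator.

    Per pollutant, d = 1 - discharge/AC; combined across pollutants either
    by the most binding pollutant (``min``, the conservative default) or by
    the vector rule used elsewhere in the tree (``rms``).
    """
    if set(results) != set(discharges):
        only_r = sorted(set(results) - set(discharges))
        only_d = sorted(set(discharges) - set(results))
        raise ValidationError(
            f"pollutant sets differ: capacity-only {only_r}, discharge-only {only_d}"
        )
    if not results:
        raise ValidationError("at least one pollutant is required")
    ds = []
    for name in sorted(results):
        ac = results[name]
        if isinstance(ac, CapacityResult):
            ac = ac.capacity
        if not ac > 0:
            raise ValidationError(f"pollutant {name!r}: capacity must be positive")
        ds.append(1.0 - discharges[name] / ac)
    if combine == "min":
        return min(ds)
    if combine == "rms":
        return aggregate(ds)
    raise ValidationError(f"unknown combine rule {combine!r} (expected 'min' or 'rms')")
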