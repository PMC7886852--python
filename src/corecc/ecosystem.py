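"""Ecosystem-service support estimators: Sum LAI, coral cover, fish density.

Terrestrial ecosystem service level is proxied by Sum LAI, the area-weighted
mean leaf area index over land-cover types,

    L_S = sum_i L_i * A_i / A_total,

using empirical per-type mean LAI values.  Coral-reef service level is
measured from field surveys: hard-coral coverage from point-intercept
transects (fraction of M sampled points intercepting hard coral, as a
percent) and reef-fish density from belt transects (count per swept area
2*L*W, the factor 2 covering both sides of the line).  Species counts need
no estimator and pass straight into indicator pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError

#: Empirical mean leaf area index by land-cover type (m^2/m^2).
DEFAULT_LAI: dict[str, float] = {
    "Farmland": 3.0,
    "Garden": 3.0,
    "Woodland": 5.0,
    "Grassland": 2.0,
    "Wetland": 6.5,
    "Construction land": 0.5,
    "Other land": 1.0,
}


@dataclass
class LandCoverComposition:
    """Areas by land-cover type; any consistent area unit."""

    areas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, a in self.areas.items():
            if a < 0:
                raise ValidationError(f"land-cover area for {t!r} must be >= 0, got {a}")
        if not sum(self.areas.values()) > 0:
            raise ValidationError("total land-cover area must be positive")

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))


@dataclass(frozen=True)
class PointInterceptTransect:
    """One point-intercept survey line: n hard-coral hits out of M points."""

    id: str
    n: int
    M: int

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValidationError(f"transect {self.id!r}: M must be positive")
        if not (0 <= self.n <= self.M):
            raise ValidationError(
                f"transect {self.id!r}: n must lie in [0, M], got n={self.n}, M={self.M}"
            )


@dataclass(frozen=True)
class BeltTransect:
    """One belt survey: N fish along a line of length L, one-side width W (m)."""

    id: str
    N: int
    L: float
    W: float

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValidationError(f"transect {self.id!r}: N must be >= 0")
        if not (self.L > 0 and self.W > 0):
            raise ValidationError(
                f"transect {self.id!r}: L and W must be positive, got L={self.L}, W={self.W}"
            )


def sum_lai(
    comp: LandCoverComposition, table: Mapping[str, float] | None = None
) -> float:
    """Area-weighted mean LAI over the composition's cover types.

    Support value for the Sum-LAI indicator; the pressure end is the target
    value set by planning or a reef-health standard.
    """
    if table is None:
        table = DEFAULT_LAI
    missing = [t for t in comp.areas if t not in table]
    if missing:
        raise ValidationError(f"cover types missing from the LAI table: {missing}")
    for t, L in table.items():
        if L < 0:
            raise ValidationError(f"LAI for {t!r} must be >= 0, got {L}")
    total = comp.total
    return float(sum(table[t] * a for t, a in comp.areas.items()) / total)


def hard_coral_coverage(t: PointInterceptTransect) -> float:
    """Hard-coral coverage (%) on one point-intercept transect: 100 * n/M."""
    return 100.0 * t.n / t.M


def fish_density(t: BeltTransect) -> float:
    """Reef-fish density (fish/m^2) on one belt transect: N / (2*L*W)."""
    return t.N / (2.0 * t.L * t.W)


def pool_transects(
    values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Pool per-transect estimates into one support value.

    Effort-weighted mean; equal weights by default.
    """
    vals = list(values)
    if not vals:
        raise ValidationError("cannot pool an empty list of transect estimates")
    if weights is None:
        return float(sum(vals) / len(vals))
    w = list(weights)
    if len(w) != len(vals):
        raise ValidationError("weights and values differ in length")
    if any(x <= 0 for x in w):
        raise ValidationError("pooling weights must be positive")
    return float(sum(v * wi for v, wi in zip(vals, w)) / sum(w))
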