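"""Available-water budget: the support end of the water-resource indicator.

The total available water resource W_AR is the sum of whatever supply
components the island draws on — canonically available ground water (W_G),
water transferred in (W_T), reclaimed wastewater (W_Re) and desalinated sea
water (W_D) — but the component list is open, so e.g. available surface
water can simply be added as another named component.  Units are a tag
(typically m^3/a) checked for pressure/support consistency, never
converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

CANONICAL_COMPONENTS = ("ground_water", "transferred_in", "reclaimed_wastewater", "desalinated")


@dataclass
class WaterBudget:
    """Named non-negative supply components sharing one units tag."""

    components: dict[str, float] = field(default_factory=dict)
    units: str = "m3/a"

    def __post_init__(self) -> None:
        for name, value in self.components.items():
            if value < 0:
                raise ValidationError(
                    f"water budget component {name!r} must be non-negative, got {value}"
                )


def available_water(budget: WaterBudget) -> float:
    """Total available water W_AR: the sum of all configured components.

    This is the support value for the water-resource indicator; the
    pressure end is the annual water consumption of the total population.
    """
    return float(sum(budget.components.values()))
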