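"""Exception hierarchy shared across the package."""


class CoreCCError(Exception):
    """Base class for all package errors."""


class ValidationError(CoreCCError):
    """Invalid data values (negative support, n > M, bad fractions, ...)."""


class ConfigError(CoreCCError):
    """Invalid run configuration; ``.violations`` lists every problem found."""

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations: list[str] = violations or []


class StructuralError(CoreCCError):
    """Malformed indicator tree (empty dimension, orphan indicator, ...)."""


class InfeasibleError(CoreCCError):
    """Load-allocation LP infeasible; ``.violated_areas`` names the areas."""

    def __init__(self, message: str, violated_areas: list[str] | None = None):
        super().__init__(message)
        self.violated_areas: list[str] = violated_areas or []
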