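"""Exception hierarchy shared across the package."""


class PdcGrowthError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PdcGrowthError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class RangeError(PdcGrowthError, ValueError):
    """An index value lies outside the span of a reference table."""


class SchemaError(PdcGrowthError, ValueError):
    """An input table is missing required columns or is otherwise unreadable."""


class RecordError(PdcGrowthError, ValueError):
    """A single record fails validation badly enough to be unprocessable."""


class DesignError(PdcGrowthError, ValueError):
    """A regression design is degenerate (e.g. an empty exposure cell)."""


class InferenceError(PdcGrowthError, ValueError):
    """Valid point estimates exist but inference is impossible (e.g. one cluster)."""


class ConfigError(PdcGrowthError, ValueError):
    """A run or simulation configuration is internally inconsistent."""
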