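"""Exception hierarchy for the pipeline.

Every error raised on a user-facing path derives from :class:`KrqolError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class KrqolError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(KrqolError):
    """Input table does not have the required columns."""


class ValidationError(KrqolError):
    """A cell value is missing or outside its declared range."""


class ConfigError(KrqolError):
    """Variable or simulation configuration is malformed."""


class DegenerateDataError(KrqolError):
    """Data admits no meaningful split or test (e.g. single-valued variable,
    empty contingency margin, consequent present in all or no participants)."""


class UndefinedMetricError(KrqolError):
    """A rule metric is undefined for the given counts (zero denominator)."""
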