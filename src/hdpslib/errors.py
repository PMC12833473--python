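"""Exception hierarchy shared across the package."""


class HdpsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HdpsError):
    """A required column/role is missing or malformed in an input table."""


class EmptyInputError(HdpsError):
    """An input table contains no records."""


class ConfigError(HdpsError):
    """Inconsistent or invalid configuration (e.g. mismatched dimension labels)."""


class AlignmentError(HdpsError):
    """Patient sets of two tables that must align do not."""


class EstimationError(HdpsError):
    """A model fit failed or its preconditions are not met."""


class ScenarioError(HdpsError):
    """A simulation scenario is degenerate (single arm, no events, ...)."""
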