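"""Exception hierarchy shared across the pipeline."""


class MonoconnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MonoconnError):
    """A configuration value violates an invariant (names the offending parameter)."""


class DesignError(MonoconnError):
    """The epoch design is inconsistent with the time series (names the cell)."""


class DegenerateSignalError(MonoconnError):
    """A region's signal is degenerate (zero variance or zero mean); names the region."""


class SchemaError(MonoconnError):
    """Input tables do not share the expected node set / column schema."""
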