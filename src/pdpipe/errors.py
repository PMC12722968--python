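"""Exception hierarchy shared across the pipeline stages."""


class PdpipeError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PdpipeError):
    """Input file violates the expected tabular schema (e.g. no label column)."""


class ParseError(PdpipeError):
    """A cell could not be parsed as numeric or a recognized missing token."""


class ConfigError(PdpipeError):
    """A configuration value is out of its legal range or inconsistent."""


class StratificationError(PdpipeError):
    """A class is absent (or too small) in a requested stratified partition."""


class StatsError(PdpipeError):
    """Column statistics cannot be computed (e.g. an all-missing column)."""


class ContractError(PdpipeError):
    """Caller violated an operation's precondition (shape/name mismatch)."""


class EmptyDatasetError(PdpipeError):
    """Record cleaning removed every row."""


class DegenerateClassError(PdpipeError):
    """A class has too few rows for per-class statistics."""


class TrainingError(PdpipeError):
    """Model training failed (divergence, non-finite gradient)."""
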