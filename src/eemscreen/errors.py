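"""Shared exception types."""


class EemScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EemScreenError):
    """Invalid configuration or missing prerequisite artifact."""


class InputError(EemScreenError):
    """A value outside the domain of an operation (non-positive potency, etc.)."""


class SchemaError(EemScreenError):
    """A table is missing required columns."""


class DegenerateDatasetError(EemScreenError):
    """A dataset lacks one of the two classes, or is too small to use."""


class UndefinedMetricError(EemScreenError):
    """A metric is undefined for the given confusion counts."""


class PipelineError(EemScreenError):
    """A pipeline stage failed; the message names the stage."""
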