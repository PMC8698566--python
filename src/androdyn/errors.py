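"""Typed exceptions raised across the pipeline."""


class AndrodynError(Exception):
    """Base class for all package errors."""


class FormatError(AndrodynError):
    """A file does not match the expected dialect/layout."""


class IngestionError(AndrodynError):
    """A file parses but violates a table invariant (e.g. duplicate id)."""


class ParameterError(AndrodynError, ValueError):
    """An argument is outside its documented domain."""


class PipelineError(AndrodynError):
    """A stage cannot proceed (empty universe, empty filter result, ...)."""
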