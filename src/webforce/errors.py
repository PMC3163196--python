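"""Typed exception hierarchy.

Every failure mode the engine can diagnose raises a subclass of
:class:`WebforceError`, so callers (and the CLI) can catch one type and
report a clean message instead of a traceback.
"""


class WebforceError(Exception):
    """Base class for all webforce errors."""


class SchemaError(WebforceError):
    """A model-definition file failed to parse or violates the schema."""


class ModelValidationError(WebforceError):
    """A structurally parseable model violates a semantic invariant
    (dangling reference, missing protocol, level-2 prevalences not
    partitioning the diagnosed population, ...)."""


class UnknownIdError(WebforceError, KeyError):
    """An attribute or competency id does not exist in the model."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return Exception.__str__(self)


class LevelMixError(WebforceError, ValueError):
    """Attributes from different WEB levels were passed where a single
    level is required."""


class MappingCoverageError(WebforceError):
    """A delivery scenario does not cover a competency with nonzero
    demand, or its shares do not sum to one."""


class MissingParamsError(WebforceError):
    """Workforce parameters are missing for an occupation with demand."""


class EnumerationCapError(WebforceError):
    """The number of patient types exceeds the configured enumeration
    cap."""
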