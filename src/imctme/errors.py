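"""Exception hierarchy.

All package-raised errors derive from :class:`ImctmeError` so callers (and
the CLI) can distinguish configuration problems (exit code 2) from data
problems (exit code 3) and stage failures (exit code 4).
"""


class ImctmeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ImctmeError):
    """Invalid configuration: bad parameter values, malformed gating trees,
    interaction plans naming unknown phenotypes, and similar."""


class SchemaError(ImctmeError):
    """An input file does not conform to the documented schema
    (missing required column, page-count mismatch, missing channel)."""


class ParseError(ImctmeError):
    """A value in an input file could not be parsed (reported with row)."""


class DataError(ImctmeError):
    """Structurally valid input that violates an operation's contract
    (centroid outside the raster, sample without FOXL2+ cells, ...)."""


class ContractViolationError(DataError):
    """An operation received input outside its stated domain."""


class DegenerateDistributionError(DataError):
    """A marker's intensity distribution cannot support thresholding."""


class DegenerateShapeError(DataError):
    """A region is too small for morphology features (< 4 pixels)."""


class NoValleyError(DataError):
    """The fraction density is unimodal: no valley threshold exists.
    Supply a manual threshold instead."""


class StageError(ImctmeError):
    """A pipeline stage failed; the manifest records which one."""
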