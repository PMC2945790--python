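"""Exception hierarchy for the GVF toolkit.

All toolkit errors derive from :class:`GvfError` so callers can catch one
base class.  Parse-time errors carry the 1-based line number of the
offending input line when it is known.
"""

from __future__ import annotations


class GvfError(Exception):
    """Base class for all toolkit errors."""


class GvfParseError(GvfError):
    """A line of GVF/GFF3 text could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ColumnCountError(GvfParseError):
    """A feature line did not have exactly nine tab-separated columns."""


class CoordinateError(GvfParseError):
    """Start/end columns are non-integer, non-positive, or end < start."""


class AttributeParseError(GvfParseError):
    """Malformed column-9 attribute syntax (missing '=', bad typed value)."""


class DuplicateTagError(AttributeParseError):
    """A recognized attribute tag appeared more than once on one line."""


class MandatoryAttributeError(GvfError):
    """A record is missing a mandatory attribute (the ID tag)."""


class PragmaError(GvfParseError):
    """A '##' pragma line is malformed."""


class DateFormatError(PragmaError):
    """A file-date pragma value is not an ISO 8601 YYYY-MM-DD date."""


class OntologyError(GvfError):
    """Base class for ontology problems."""


class MalformedOntologyError(OntologyError):
    """The OBO input is structurally broken (cycle, dangling is_a target)."""


class UnknownTermError(OntologyError):
    """A term name or accession is not present in the loaded ontology."""


class ConversionError(GvfError):
    """A format conversion cannot proceed (e.g. unnamed multi-sample VCF)."""


class ConfigurationError(GvfError):
    """A user-supplied configuration value is invalid (e.g. effect map)."""


class GeneratorError(GvfError):
    """The synthetic-data generator was asked for something impossible."""
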