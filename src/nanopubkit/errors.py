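"""Exception hierarchy.

Every error raised by the package derives from :class:`NanopubKitError` and
carries a short machine-parseable ``code`` used by the command-line interface
for one-line error reporting.
"""

from __future__ import annotations


class NanopubKitError(Exception):
    """Base class for all package errors."""

    code = "error"


class InvalidArgumentError(NanopubKitError):
    code = "invalid-argument"


class ResolutionError(NanopubKitError):
    """A CURIE prefix could not be resolved."""

    code = "resolution-error"


class ParseError(NanopubKitError):
    """A document could not be parsed; ``line`` is set when known."""

    code = "parse-error"

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ValidationError(NanopubKitError):
    """A record or context violates its schema; ``row`` is set for table rows."""

    code = "validation-error"

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class SchemaError(NanopubKitError):
    """A tabular input is missing a required column."""

    code = "schema-error"


class AssemblyError(NanopubKitError):
    code = "assembly-error"


class StructureError(NanopubKitError):
    """A nanopublication document does not have the expected graph structure."""

    code = "structure-error"


class MappingError(NanopubKitError):
    """An IRI does not match the namespace pattern it should be rewritten from."""

    code = "mapping-error"


class IntegrationError(NanopubKitError):
    """A required fixture graph is missing for an integration stage."""

    code = "integration-error"

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class CycleError(NanopubKitError):
    """The subclass relation of an ontology fixture contains a cycle."""

    code = "cycle-error"
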