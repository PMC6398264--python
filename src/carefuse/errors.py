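"""Exception hierarchy."""


class CarefuseError(Exception):
    """Base class for all package errors."""


class OntologyFormatError(CarefuseError):
    """The ontology file could not be parsed."""


class OntologyValidationError(CarefuseError):
    """The ontology violates a structural invariant (e.g. a subclass cycle)."""


class TermLookupError(CarefuseError, KeyError):
    """An IRI is not present in the registry."""


class CodeSyntaxError(CarefuseError, ValueError):
    """A diagnosis code does not match the ICD-10 syntax."""


class MappingValidationError(CarefuseError):
    """A mapping rule references an unknown term or unsupported construct."""


class MintingError(CarefuseError):
    """An IRI template could not be instantiated (e.g. null key)."""


class MaterializationError(CarefuseError):
    """A mapping rule references a missing table or column."""


class UnsupportedQueryError(CarefuseError):
    """The triple-pattern query cannot be answered with inference enabled."""


class QueryParseError(CarefuseError, ValueError):
    """A text query string is malformed; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class IngestionError(CarefuseError):
    """A document could not be added to the index (e.g. duplicate id)."""


class PatternPackError(CarefuseError):
    """A pattern pack file is invalid."""


class AlignmentError(CarefuseError):
    """Annotated corpus and ground truth do not describe the same documents."""


class PatientNotFoundError(CarefuseError, KeyError):
    """The requested patient is not present in the integrated graph."""


class ConfigError(CarefuseError, ValueError):
    """A simulation or run configuration is invalid."""
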