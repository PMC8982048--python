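"""Exception hierarchy shared across modules."""


class OntoEnrichError(Exception):
    """Base class for all package errors."""


class ParseError(OntoEnrichError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(OntoEnrichError):
    """A structural invariant was violated (e.g. a cycle in the DAG)."""


class TermNotFoundError(OntoEnrichError):
    """Identifier does not resolve to any term in the ontology."""


class ObsoleteTermError(OntoEnrichError):
    """Term is obsolete and has no replaced_by target."""


class DomainError(OntoEnrichError):
    """Numeric arguments violate a stated precondition."""


class EmptyOverlapError(OntoEnrichError):
    """No input gene lies in the reference universe."""


class AssemblyMismatchError(OntoEnrichError):
    """Region query assembly differs from the gene table assembly."""
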