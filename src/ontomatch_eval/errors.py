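"""Exception hierarchy shared across the toolkit."""


class OntomatchError(Exception):
    """Base class for all toolkit errors."""


class FormatError(OntomatchError):
    """An input file could not be parsed in its declared format."""


class ValidationError(OntomatchError):
    """Parsed input violates a structural invariant (cycles, duplicate
    identifiers, missing roots, non-top-level classes in a top-level
    mapping table, ...)."""


class UsageError(OntomatchError):
    """An operation was called with arguments outside its contract."""
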