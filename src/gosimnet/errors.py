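"""Exception hierarchy.

All library errors derive from :class:`GosimnetError` so callers (and the
CLI) can catch one base class. Usage/configuration problems are separated
from data problems because the CLI maps them to different exit codes.
"""


class GosimnetError(Exception):
    """Base class for all errors raised by gosimnet."""


class UsageError(GosimnetError):
    """Invalid arguments, unknown measure/format names, bad configuration."""


class ConfigurationError(UsageError):
    """A fixture spec or training configuration violates its invariants."""


class DataError(GosimnetError):
    """Problems with input data files or their contents."""


class OboParseError(DataError):
    """Malformed OBO input; carries the offending line when known."""


class OntologyIntegrityError(DataError):
    """The parsed ontology violates a structural invariant (e.g. a cycle)."""


class UnknownTermError(DataError, KeyError):
    """A term id is not present in the loaded ontology."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return Exception.__str__(self)


class NamespaceMismatchError(UsageError):
    """Two terms from different GO namespaces were compared."""


class GafParseError(DataError):
    """Malformed GAF/TSV annotation input."""


class EmptyCorpusError(DataError):
    """No usable annotations survived parsing and filtering."""


class UndefinedICError(DataError):
    """Information content requested for a term with zero annotations."""


class MissingAnnotationError(DataError):
    """A gene required for a similarity computation has no annotations."""


class AlignmentError(DataError):
    """Input similarity matrices do not cover the same gene pairs."""


class DegenerateModelError(UsageError):
    """An integration model cannot score a pair (e.g. all selected weights 0)."""
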