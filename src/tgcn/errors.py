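"""Exception hierarchy shared across the package.

Every error raised by tgcn derives from :class:`TGCNError`, so callers
(notably the CLI) can catch one type and map it to a diagnostic exit.
"""


class TGCNError(Exception):
    """Base class for all tgcn errors."""


class IntegrityError(TGCNError):
    """A structural invariant of the temporal-network model was violated."""


class FormatError(TGCNError):
    """An input file does not conform to its declared dialect."""


class GeneLookupError(TGCNError):
    """A requested gene is absent from the object being queried."""


class ResolutionError(TGCNError):
    """Gene aliases could not be resolved against the reference table."""


class AmbiguousAliasError(ResolutionError):
    """An alias maps to more than one canonical identifier."""


class AlignmentError(TGCNError):
    """Expression vectors are not sample-aligned (length mismatch)."""


class ConfigurationError(TGCNError):
    """Invalid run parameters (gene count, threshold range, ...)."""


class EmptyNetworkError(TGCNError):
    """No stratum survived filtering; no network can be built."""


class ValidationError(TGCNError):
    """A synthetic design or metric input is internally inconsistent."""
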