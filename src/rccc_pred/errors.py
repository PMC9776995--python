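"""Exception hierarchy shared across the pipeline.

Every error raised on purpose by this package derives from :class:`RcccError`
so the CLI can catch one type and exit with a one-line diagnostic.
"""


class RcccError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RcccError):
    """Malformed on-disk input (FASTA, catalog CSV, feature CSV)."""


class ContractError(RcccError):
    """A documented precondition or invariant was violated by the caller."""


class MutationError(RcccError):
    """A mutation could not be applied to its reference sequence."""
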