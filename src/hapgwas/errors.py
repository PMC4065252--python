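"""Exception hierarchy for hapgwas.

All errors raised on user input derive from :class:`HapgwasError` so callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class HapgwasError(Exception):
    """Base class for all hapgwas errors."""


class FormatError(HapgwasError):
    """A file or table does not conform to the documented plain-text format."""


class ValidationError(HapgwasError):
    """Parsed data violate a container invariant (e.g. negative RPKM)."""


class PloidyError(FormatError):
    """A VCF genotype is not haploid (single-allele GT)."""


class DegenerateDataError(HapgwasError):
    """An operation received data on which its result is undefined.

    Examples: a locus with only missing calls, a constant expression vector
    for correlation, or a focal gene whose values all tie with the mean.
    """


class PreconditionError(HapgwasError):
    """An operation's stated precondition does not hold."""


class TriplicateRejectionError(HapgwasError):
    """A qPCR triplicate failed the replicate-agreement quality check.

    Carries the indices of the offending replicates in ``indices``.
    """

    def __init__(self, message: str, indices: tuple[int, ...]):
        super().__init__(message)
        self.indices = indices
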