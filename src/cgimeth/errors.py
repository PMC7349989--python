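"""Exception hierarchy shared across the package.

Validation problems (malformed input files, out-of-range values) and
computation problems (e.g. a saturated ddPCR well with no finite point
estimate) are kept distinct so the command line can map them to different
exit codes.
"""


class CgimethError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(CgimethError):
    """An input file or parameter violates its contract."""

    exit_code = 2


class ComputationError(CgimethError):
    """The requested quantity cannot be computed from the given data."""

    exit_code = 3


class SaturatedWellError(ComputationError):
    """All droplets positive: the Poisson point estimate is unbounded."""
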