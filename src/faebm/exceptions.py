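"""Exception hierarchy for the package.

All errors raised by faebm derive from :class:`FaebmError` so callers can
catch pipeline failures with a single except clause while still
distinguishing schema problems from numerical failures.
"""


class FaebmError(Exception):
    """Base class for all faebm errors."""


class SchemaError(FaebmError):
    """Input table or artifact does not match the expected schema."""


class ValidationError(FaebmError):
    """Values present but invalid (wrong range, wrong group label, ...)."""


class SampleSizeError(FaebmError):
    """Too few observations for the requested fit."""


class DegenerateDataError(FaebmError):
    """Data admit no fit (zero variance, constant covariate, ...)."""


class EstimationFailureError(FaebmError):
    """An estimation procedure failed irrecoverably (e.g. every bootstrap
    replicate collapsed, or a majority of cross-validation replicates
    errored)."""
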