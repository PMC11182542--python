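"""Exception hierarchy used across the package."""


class MultitrialError(Exception):
    """Base class for all package errors."""


class ValidationError(MultitrialError, ValueError):
    """Invalid input data or configuration; the message names the offending field."""


class ContractViolationError(MultitrialError, RuntimeError):
    """A pipeline-stage precondition was violated (e.g. imputing a record that
    should have been excluded upstream)."""


class NonEstimableError(MultitrialError, ValueError):
    """A requested contrast or model cannot be estimated from the data at hand
    (missing arm, single outcome level)."""


class TooLargeError(MultitrialError, ValueError):
    """An exhaustive computation was requested on an instance above its size cap."""
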