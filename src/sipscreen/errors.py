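"""Exception hierarchy shared across the package.

All errors raised deliberately by sipscreen derive from :class:`SipScreenError`
so callers (and the CLI) can distinguish anticipated failures from bugs.
"""


class SipScreenError(Exception):
    """Base class for all sipscreen errors."""


class FormatError(SipScreenError, ValueError):
    """A file does not conform to the expected dialect (missing columns, etc.)."""


class ValidationError(SipScreenError, ValueError):
    """Input values violate a documented precondition or invariant."""


class ConfigurationError(SipScreenError):
    """The experiment layout is incomplete (e.g. a missing fraction sample)."""


class UndefinedStatisticError(SipScreenError):
    """A statistic is undefined for the given counts (zero margins without a
    continuity-correction policy that resolves them)."""
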