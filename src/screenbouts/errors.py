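"""Exception hierarchy shared across the pipeline stages."""


class ScreenboutsError(Exception):
    """Base class for all package-specific errors."""


class ContractViolationError(ScreenboutsError, ValueError):
    """An operation's precondition was violated (e.g. unsorted input)."""


class EmptyStreamError(ScreenboutsError, RuntimeError):
    """A log file contained data rows but none could be parsed.

    Distinct from an empty-but-valid file (header only), which yields an
    empty :class:`~screenbouts.state_logs.EventStream` without error.
    """


class UnsupportedOSError(ContractViolationError):
    """An operation received a stream from the wrong operating system."""
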