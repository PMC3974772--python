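"""Exception types shared across the package."""


class NosepokeError(Exception):
    """Base class for all package-specific errors."""


class EventLogParseError(NosepokeError):
    """Raised when an event-log stream cannot be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class AnimalExcludedError(NosepokeError):
    """An animal's data cannot be normalized and must be excluded.

    Raised when the baseline is degenerate: the animal never investigated
    the port during background sessions (basal activity 0), or resided
    solely in one chamber of a three-chamber arena (control-zone time 0).
    """


class MetricUndefinedError(NosepokeError):
    """A behavioral statistic is undefined for the given counts
    (e.g. a success rate with zero recorded trials)."""
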