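"""Exception hierarchy shared across the toolkit."""


class CellwatchError(Exception):
    """Base class for all cellwatch errors."""


class GridError(CellwatchError):
    """Time grid is non-uniform, non-increasing, or misaligned between series."""


class ParameterError(CellwatchError):
    """An operation was called with an out-of-range or inconsistent parameter."""


class ChannelUnavailableError(CellwatchError):
    """A required channel is missing or inactive."""


class GroupUnavailableError(CellwatchError):
    """An aggregation group has no active sensors."""


class ValidationError(CellwatchError):
    """Input data violates a structural invariant."""
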