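"""Exception hierarchy.

Every error raised by calpop derives from :class:`CalpopError`, so callers
can catch pipeline failures without masking programming errors.
"""


class CalpopError(Exception):
    """Base class for all calpop errors."""


class ConfigError(CalpopError):
    """Invalid configuration value; the message names the offending field."""


class ParseError(CalpopError):
    """Malformed input file; the message locates the offending row/column."""


class DegenerateBaselineError(CalpopError):
    """A baseline is unusable (non-positive F0, zero SD, too few samples)."""


class WindowError(CalpopError):
    """A time window is empty, inverted, or outside the data it indexes."""


class EmptyEpochError(CalpopError):
    """No usable trials remain after boundary exclusion."""


class InsufficientDataError(CalpopError):
    """Too few trials/samples for the requested statistic."""


class RegistrationError(CalpopError):
    """Neuron identities cannot be matched across results or sessions."""


class AlignmentError(CalpopError):
    """Two epoch tensors do not share a frame grid or neuron set."""


class LabelError(CalpopError):
    """Class labels are degenerate (single class, empty class)."""


class SplitError(CalpopError):
    """A consecutive session split left one half without events."""
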