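"""Exception hierarchy for penkit.

All penkit-raised errors derive from :class:`PenError` so callers can
catch the whole family; plain ``ValueError`` is reserved for domain
errors on scalar arguments (e.g. a non-positive distance).
"""


class PenError(Exception):
    """Base class for all penkit errors."""


class ParseError(PenError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PenError):
    """Parsed content violates an invariant (asymmetry, length mismatch...)."""


class TopologyError(PenError):
    """Frames of an ensemble disagree on residue/atom topology."""


class ConfigurationError(PenError):
    """An invalid metric/channel/parameter combination was requested."""


class TransitionUndefinedError(PenError):
    """A transition point was requested on a profile that never crosses it."""
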