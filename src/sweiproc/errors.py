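"""Exception hierarchy for sweiproc."""


class SweiprocError(Exception):
    """Base class for all package errors."""


class ParameterError(SweiprocError, ValueError):
    """An argument violates a precondition (wrong sign, out of range, bad shape)."""


class StateError(SweiprocError, RuntimeError):
    """The operation cannot proceed in the current data state.

    Raised e.g. when a slow-time filter is applied to non-uniformly sampled
    motion data (reverberation-frame repair must run first), or when every
    frame of an ensemble is flagged bad.
    """


class ValidationError(SweiprocError, ValueError):
    """A container or payload failed metadata validation.

    The message lists *all* missing/invalid fields at once.
    """


class LowConfidenceError(SweiprocError, RuntimeError):
    """A correlation-based measurement is too weak to trust (peak below threshold)."""
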