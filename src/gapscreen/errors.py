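"""Exception hierarchy for gapscreen."""


class GapscreenError(Exception):
    """Base class for all gapscreen errors."""


class FormatError(GapscreenError):
    """A pose table or SDF file violates the expected schema."""


class ContractError(GapscreenError):
    """Caller violated an operation's preconditions (mixed ids, mismatched atoms...)."""


class DegenerateStackError(GapscreenError):
    """A stack is too small or too uniform for the requested descriptor
    (single-pose stack, native phase swallowing every pose, zero score spread)."""


class EvaluationError(GapscreenError):
    """A screening evaluation cannot be performed (single-class labels, empty input)."""


class GeometryError(GapscreenError):
    """An operation needs geometric data (coordinates or precomputed RMSDs)
    that the stack does not carry."""
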