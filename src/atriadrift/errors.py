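"""Exception types raised by the simulator."""


class AtriaDriftError(RuntimeError):
    """Base class for package errors."""


class IntegrationError(AtriaDriftError):
    """Numerical failure (NaN/overflow or state-invariant violation)."""


class StimulusError(AtriaDriftError):
    """A stimulation protocol failed to elicit an action potential."""


class ProtocolError(AtriaDriftError):
    """A pacing/initiation protocol failed to reach its stated condition."""


class AnalysisError(AtriaDriftError):
    """A trace/geometry analysis could not be performed on the given data."""


class ConstructionError(AtriaDriftError):
    """A geometry builder produced an invalid (e.g. disconnected) result."""
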