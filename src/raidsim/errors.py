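"""Exception hierarchy for raidsim."""


class RaidsimError(Exception):
    """Base class for all raidsim errors."""


class ParameterError(RaidsimError, ValueError):
    """An operation was called with invalid parameter values."""


class ConfigurationError(RaidsimError, ValueError):
    """A simulation/experiment configuration violates its invariants."""


class NetworkGenerationError(RaidsimError, RuntimeError):
    """Network generation exhausted its retry budget without producing a valid graph."""


class FormatError(RaidsimError, ValueError):
    """A network or role file could not be parsed, or violates graph invariants.

    The message names the offending line or element where possible.
    """
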