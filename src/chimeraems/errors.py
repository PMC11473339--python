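class ChimeraEMSError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChimeraEMSError):
    """A configuration value violates an invariant (named in the message)."""


class SimulationError(ChimeraEMSError):
    """The simulator could not honour the requested design."""


class PileupParseError(ChimeraEMSError):
    """A pileup line could not be parsed; message carries the line number."""


class InputError(ChimeraEMSError):
    """User-supplied data is inconsistent (unknown sample, bad record, ...)."""
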