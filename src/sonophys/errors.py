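"""Exception hierarchy shared across the package."""


class SonophysError(Exception):
    """Base class for all package-specific errors."""


class InvalidMediumError(SonophysError, ValueError):
    """Acoustic medium with non-positive density or speed of sound."""


class UnsupportedModalityError(SonophysError, ValueError):
    """Operation applied to a stimulation modality it is not defined for."""


class DomainError(SonophysError, ValueError):
    """Argument outside the physical domain of the operation."""


class ProtocolError(SonophysError, ValueError):
    """Stimulation-protocol fields violate their invariants."""


class TraceFormatError(SonophysError, ValueError):
    """Trace file malformed (non-uniform sampling, bad columns, ...)."""


class TraceMetadataError(SonophysError, ValueError):
    """Sidecar metadata missing or inconsistent with the trace."""


class DegenerateWindowError(SonophysError, ValueError):
    """Analysis window empty or too short for the requested statistic."""


class DegenerateDesignError(SonophysError, ValueError):
    """Statistical design without enough variation to be fit (e.g. constant x)."""


class UnbalancedDesignError(SonophysError, ValueError):
    """Factorial design with empty cells; message names the offending cell."""


class ConfigError(SonophysError, ValueError):
    """Pipeline configuration failed validation."""
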