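"""Exception types shared across the package."""


class SSPTError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(SSPTError, ValueError):
    """A synthetic-crystal or run specification violates its invariants."""


class DegenerateTraceError(SSPTError, ValueError):
    """An intensity trace is constant or otherwise unusable."""


class NoTransitionError(SSPTError, ValueError):
    """No derivative peak rises above the noise floor."""


class NoInflectionError(SSPTError, ValueError):
    """A trajectory has no interior maximum of its first derivative."""


class SolverFailureError(SSPTError, RuntimeError):
    """The ODE integrator failed or produced unphysical concentrations."""


class CalibrationError(SSPTError, ValueError):
    """A standard curve cannot be fit or is not a valid calibration."""
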