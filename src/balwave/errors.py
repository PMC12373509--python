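"""Exception types shared across the package."""


class BalwaveError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BalwaveError, ValueError):
    """A model or analysis parameter violates its documented bounds."""


class NoFrontError(BalwaveError, ValueError):
    """A profile carries no detectable front (flat within the noise floor)."""


class NoPlateauError(BalwaveError, ValueError):
    """No invaded plateau exists behind the front (front too close to the boundary)."""


class InsufficientDataError(BalwaveError, ValueError):
    """Too few valid frames/points for the requested fit."""


class FitError(BalwaveError, RuntimeError):
    """A nonlinear fit failed to converge or produced unphysical values."""


class SimulationError(BalwaveError, RuntimeError):
    """The simulator produced non-finite fields; carries a step diagnostic."""
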