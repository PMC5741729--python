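"""Exception hierarchy for fibrilsim."""


class FibrilsimError(Exception):
    """Base class for all fibrilsim errors."""


class InvalidProfileError(FibrilsimError):
    """A domain stiffness profile does not have exactly 15 valid entries."""


class InvalidSiteError(FibrilsimError):
    """A cryptic-binding-site index lies outside the Type III range 1..15."""


class IllegalBindError(FibrilsimError):
    """Attempted FN-FN attachment at an ineligible position or molecule."""


class ContourLimitError(FibrilsimError):
    """Domain stretch at or beyond the unfolded contour length."""


class SolverError(FibrilsimError):
    """Quasi-static equilibrium solve failed to converge."""

    def __init__(self, message: str, residual: float | None = None,
                 time: float | None = None):
        super().__init__(message)
        self.residual = residual
        self.time = time


class TopologyError(FibrilsimError):
    """Fibril bond network is not a single connected tree."""


class WindowError(FibrilsimError):
    """An averaging window is longer than the available trajectory."""


class FitError(FibrilsimError):
    """Too few points to fit the requested quantity."""


class ConfigError(FibrilsimError):
    """Run configuration failed validation."""


class CalibrationError(FibrilsimError):
    """No parameter set in the searched box met the calibration targets."""

    def __init__(self, message: str, best: dict | None = None):
        super().__init__(message)
        self.best = best or {}
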