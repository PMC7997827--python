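"""Exception hierarchy for the mDoE toolbox."""


class MdoeError(Exception):
    """Base class for all toolbox errors."""


class StoichiometryError(MdoeError):
    """Elemental balance cannot be closed; carries the offending element."""

    def __init__(self, message: str, element: str | None = None):
        super().__init__(message)
        self.element = element


class InvalidParameterError(MdoeError):
    """A kinetic or model parameter violates its contract."""


class ModelEvaluationError(MdoeError):
    """The model right-hand side produced a non-finite derivative."""


class SimulationError(MdoeError):
    """Numerical integration failed; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class CalibrationError(MdoeError):
    """All optimizer starts failed, or the fit ensemble is degenerate."""


class EnsembleError(MdoeError):
    """More than half of the Monte-Carlo fits failed."""


class DesignError(MdoeError):
    """Design-space sampling or clustering failed."""


class DesignPointError(MdoeError):
    """Too many failed simulations at a single planned experiment."""


class ConfigurationError(MdoeError):
    """A study configuration violates its contract (e.g. w1 + w2 != 1)."""
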