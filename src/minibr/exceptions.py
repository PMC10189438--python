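"""Exception hierarchy for minibr."""


class MiniBRError(Exception):
    """Base class for all minibr errors."""


class InvalidParameterError(MiniBRError, ValueError):
    """A physical parameter is non-finite, negative, or otherwise out of range."""


class OutOfDomainError(MiniBRError, ValueError):
    """A query point lies outside the liquid domain."""


class SolverError(MiniBRError, RuntimeError):
    """The sparse linear solve for the flow field failed."""


class CalibrationError(MiniBRError, RuntimeError):
    """Actuator body-force calibration could not meet the target throughput."""


class LaminarGateError(MiniBRError, RuntimeError):
    """Fluid Reynolds number exceeds the laminar threshold and no override was set."""


class PackingError(MiniBRError, RuntimeError):
    """Random particle packing failed (volume fraction too high)."""

    def __init__(self, message: str, achieved_n: int = 0):
        super().__init__(message)
        self.achieved_n = achieved_n


class TimeStepError(MiniBRError, ValueError):
    """The requested time step violates the stability/accuracy bound."""


class IntegrityError(MiniBRError, RuntimeError):
    """A particle left the vessel despite wall contact and clamping."""


class ClassificationError(MiniBRError, ValueError):
    """Trajectory too short for stagnant/recirculating classification."""


class InvalidTensorError(MiniBRError, ValueError):
    """A stress tensor is asymmetric or has a non-negligible trace."""


class EmptyPopulationError(MiniBRError, ValueError):
    """No stress traces supplied to the population summary."""


class DataError(MiniBRError, ValueError):
    """Measured size data are unusable (non-positive or too few values)."""
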