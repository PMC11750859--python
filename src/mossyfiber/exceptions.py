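"""Exception types raised across the package."""


class MossyFiberError(Exception):
    """Base class for all package errors."""


class ModelConfigError(MossyFiberError, ValueError):
    """Invalid geometry, passive constants, or channel-density configuration."""


class UnknownLandmarkError(MossyFiberError, KeyError):
    """A landmark name does not resolve to any section of the cell."""


class UnknownChannelError(MossyFiberError, KeyError):
    """A density map or variant request names a channel that does not exist."""


class UnknownPresetError(MossyFiberError, KeyError):
    """Protocol preset name not found; the message lists available presets."""


class KineticsProfileUnavailable(MossyFiberError):
    """A kinetics profile slot exists but has not been populated with rate
    constants (e.g. the ``paper`` profile awaiting transcription from a
    published model deposit)."""


class SimulationDiverged(MossyFiberError, ArithmeticError):
    """The integrator produced a non-finite or runaway voltage.

    Carries the time (ms) and global segment index where divergence was
    detected.
    """

    def __init__(self, t_ms: float, segment: int, message: str = ""):
        self.t_ms = t_ms
        self.segment = segment
        super().__init__(
            message or f"simulation diverged at t={t_ms:.4g} ms, segment {segment}"
        )


class SteadyStateNotConverged(MossyFiberError):
    """Relaxation to steady state did not reach tolerance within the time cap.

    Carries the residual max |dV/dt| in mV/ms.
    """

    def __init__(self, residual: float, t_cap_ms: float):
        self.residual = residual
        self.t_cap_ms = t_cap_ms
        super().__init__(
            f"steady state not reached within {t_cap_ms:.4g} ms; "
            f"residual max|dV/dt| = {residual:.4g} mV/ms"
        )


class HalfDurationUndefined(MossyFiberError):
    """A spike's falling flank never returned to the half-amplitude level
    before the next event (or the end of the trace)."""
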