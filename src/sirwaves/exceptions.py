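"""Exception hierarchy for sirwaves.

Every error raised by the package derives from :class:`SIRWavesError`, so
callers can catch one type at the CLI boundary.
"""


class SIRWavesError(Exception):
    """Base class for all sirwaves errors."""


class ParameterError(SIRWavesError, ValueError):
    """Invalid model parameters (non-positive rates, broken conservation...)."""


class IntegrationFailure(SIRWavesError, RuntimeError):
    """The numerical integrator produced a non-finite state."""


class OrderError(ParameterError):
    """Truncation order M outside its supported range (M >= 2)."""


class TruncationBreakdownError(SIRWavesError, RuntimeError):
    """The truncated polynomial chain blew up (R exceeded N).

    Raised by :func:`sirwaves.chain_reduction.integrate_chain`; check the
    Taylor validity bound before trusting a truncated integration.
    """


class ConstantsInfeasibleError(ParameterError):
    """Integration constants place the atanh argument outside (-1, 1)."""


class UnsupportedBranchError(ParameterError):
    """E = 0 with D != 0: a formal branch of the Riccati family not supported."""


class AssumptionViolatedError(ParameterError):
    """A closed-form correction bound was requested outside its assumptions."""


class NoWaveError(ParameterError):
    """Initial conditions admit no wave (e.g. S(0) >= N for the cubic family)."""


class HorizonNotReachedError(SIRWavesError, RuntimeError):
    """I(t) is still rising at the end of the (auto-extended) time window."""


class InfeasibleSpliceError(ParameterError):
    """A wavetrain splice would start a segment with I(0) >= N."""


class DeadSpliceError(ParameterError):
    """A wavetrain splice after wave extinction (I = 0 at the splice time)."""


class ConfigError(SIRWavesError, ValueError):
    """Malformed configuration or scenario definition."""


class UnknownScenarioError(ConfigError):
    """Requested scenario name is not shipped and is not a readable path."""
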