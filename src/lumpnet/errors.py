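"""Exception hierarchy for lumpnet."""


class LumpnetError(Exception):
    """Base class for all lumpnet errors."""


class FormatError(LumpnetError):
    """A model file could not be parsed under the named standard."""


class LookupError_(LumpnetError):
    """An identifier does not exist in the model."""


class ParameterError(LumpnetError):
    """An invalid numeric parameter (e.g. non-positive carbon cap)."""


class BlockedTargetError(LumpnetError):
    """The target cannot be synthesized from the core and the medium."""

    def __init__(self, target_id: str, message: str | None = None):
        self.target_id = target_id
        super().__init__(message or f"target {target_id!r} is not producible "
                         "from the core network and the medium")


class SolverTimeoutError(LumpnetError):
    """The MILP hit its time limit; carries the best incumbent if any."""

    def __init__(self, message: str, incumbent=None):
        self.incumbent = incumbent
        super().__init__(message)


class ThermoInfeasibleError(LumpnetError):
    """Net-flux minimization infeasible under tightened directionality."""


class LumpingResidueError(LumpnetError):
    """A non-core intermediate survived lump cleanup above tolerance."""


class AssemblyError(LumpnetError):
    """A reduced/mini model could not be assembled consistently."""
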