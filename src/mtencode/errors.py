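"""Exception hierarchy shared across modules."""


class MTEncodeError(Exception):
    """Base class for all package errors."""


class ParameterError(MTEncodeError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class BoundaryError(MTEncodeError):
    """An operation needing a full neighborhood was applied at a lattice edge."""


class ConstraintError(MTEncodeError):
    """A phosphorylation-pattern constraint was violated (e.g. writing the
    central address dimer, or exceeding the kinase count)."""


class ConfigurationError(MTEncodeError):
    """A hexagon/gate configuration incompatible with the given lattice or patch."""


class SimulationError(MTEncodeError):
    """Token propagation failed to reach quiescence within the step cap."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
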