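"""Exception hierarchy."""


class PhasorTacsError(Exception):
    """Base class for all package errors."""


class ValidationError(PhasorTacsError):
    """Invalid arguments or inconsistent inputs."""


class ResolutionError(PhasorTacsError):
    """Requested mesh resolution cannot resolve the geometry."""


class PlacementError(PhasorTacsError):
    """Electrode placement failed (overlapping footprints, no scalp hit)."""


class SolverError(PhasorTacsError):
    """Linear solver failure (non-convergence, singular geometry)."""
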