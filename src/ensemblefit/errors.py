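"""Exception hierarchy for ensemblefit."""


class EnsembleFitError(Exception):
    """Base class for all package errors."""


class InputError(EnsembleFitError, ValueError):
    """Invalid user input: unknown names, malformed tables, bad arguments."""


class ValidationError(EnsembleFitError, ValueError):
    """A domain object violates one of its invariants."""


class GeometryError(EnsembleFitError, RuntimeError):
    """Geometry construction failed (e.g. ring closure beyond tolerance)."""


class UndefinedDihedralError(GeometryError):
    """Dihedral is undefined because of collinear atoms."""


class SingularityError(EnsembleFitError, RuntimeError):
    """Numerical singularity, e.g. coincident protons with r = 0."""


class DegenerateScaleError(EnsembleFitError, RuntimeError):
    """Nuisance-scale solve is degenerate (all predictions zero)."""


class ConfigurationError(EnsembleFitError, ValueError):
    """Inconsistent configuration, e.g. a zero reference spread."""
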