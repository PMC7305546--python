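"""Exception hierarchy for the pipeline."""


class EITError(Exception):
    """Base class for all package errors."""


class ValidationError(EITError, ValueError):
    """Invalid user-supplied parameter or inconsistent inputs."""


class GeometryError(EITError):
    """Ill-posed domain outline or infeasible electrode placement."""


class MeshingError(EITError):
    """Triangulation failed or violated a mesh post-condition."""


class SolverError(EITError):
    """Linear solve failed (singular or ill-conditioned system)."""


class NormalizationError(EITError):
    """A measured voltage is too close to zero to normalize."""


class ProvenanceError(EITError):
    """Artifacts from different mesh/protocol provenances were mixed."""


class TrainingError(EITError):
    """MLP optimization diverged."""
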