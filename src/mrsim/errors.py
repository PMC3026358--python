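"""Exception hierarchy shared across the toolkit.

Exit-code classes used by the CLI: configuration (2), I/O (3), numerical (4).
"""


class MrsimError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class InvalidArgumentError(MrsimError, ValueError):
    """A caller-supplied value violates a documented precondition."""

    exit_code = 2


class ConfigError(MrsimError):
    """Run configuration invalid or referencing missing inputs."""

    exit_code = 2


class FileFormatError(MrsimError):
    """Malformed input file (parse or schema failure)."""

    exit_code = 3


class UnderdeterminedError(MrsimError):
    """Point configuration does not determine a unique rigid transform
    (fewer than three pairs, or a collinear configuration)."""

    exit_code = 4


class InvalidPickError(InvalidArgumentError):
    """Surface pick farther from the mesh than the snap tolerance."""


class TrackabilityError(InvalidArgumentError):
    """Marker set cannot be tracked (fewer than three markers)."""


class RigidBodyModeError(MrsimError):
    """FEM system singular: constraints leave unremoved rigid-body modes."""

    exit_code = 4

    def __init__(self, message: str, nullspace_dim: int | None = None):
        super().__init__(message)
        self.nullspace_dim = nullspace_dim


class MeshQualityError(MrsimError):
    """Degenerate or inverted finite element."""

    exit_code = 4


class FeasibilityError(MrsimError):
    """Rejection sampling could not satisfy the requested constraints."""

    exit_code = 4


class NoCriticalForceError(MrsimError):
    """Unit load produces zero stress; no finite critical force exists."""

    exit_code = 4
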