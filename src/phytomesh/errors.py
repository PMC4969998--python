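"""Exception hierarchy.

Domain errors (open mesh where a closed one is required, unreachable
destination, a band partition too fine for the mesh resolution, ...) all
derive from :class:`PhytomeshError` so callers — in particular the CLI —
can distinguish them from programming errors.
"""


class PhytomeshError(Exception):
    """Base class for all phytomesh domain errors."""


class EmptyMeshError(PhytomeshError):
    """A mesh with no vertices or no faces where content is required."""


class MeshParseError(PhytomeshError):
    """A mesh file exists but could not be parsed."""


class NonManifoldError(PhytomeshError):
    """An edge bordered by three or more faces."""


class OpenMeshError(PhytomeshError):
    """Volume (or another closed-surface quantity) requested on an open mesh."""


class NoPathError(PhytomeshError):
    """Source and destination lie in different connected components."""


class BandPartitionError(PhytomeshError):
    """An intermediate band of the centerline partition is empty."""


class RemeshError(PhytomeshError):
    """The target resolution could not be reached."""
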