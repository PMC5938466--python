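"""Exception hierarchy for articulate3d.

Every error a pipeline can raise derives from :class:`Articulate3DError`,
so callers (and the CLI) can map each failure mode to a distinct,
actionable message.
"""


class Articulate3DError(Exception):
    """Base class for all articulate3d errors."""


class DegenerateGeometryError(Articulate3DError):
    """Geometry is degenerate: coincident axis landmarks, parallel vectors
    where a plane normal is required, or an orient landmark lying on the
    rotation axis (the in-axis rotation is then undefined)."""


class ReflectionError(Articulate3DError):
    """A structure's role-landmark quadruple has inconsistent handedness
    across specimens; a rigid rotation cannot undo a reflection."""


class TPSFormatError(Articulate3DError):
    """A TPS file is malformed: inconsistent landmark counts, 2D records,
    or unparseable coordinate lines."""


class SpecimenMatchError(Articulate3DError):
    """Two datasets share no specimen identifiers, so matching is impossible."""
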