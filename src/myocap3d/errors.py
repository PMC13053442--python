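"""Exception and warning types shared across the package."""


class MyoCapError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleSpecError(MyoCapError):
    """A phantom specification cannot be realised (e.g. requested branch
    density below one branch point per field, or fibre diameters that do not
    fit the field area). Raised instead of silently clamping."""


class EmptySegmentationError(MyoCapError):
    """Segmentation produced an all-background volume."""


class UndefinedMetricError(MyoCapError):
    """A morphometric quantity is undefined for the given input (e.g. MeanCap
    with zero branching density, tortuosity of a zero-length graph)."""


class DegenerateGeometryError(MyoCapError):
    """Geometric input is degenerate: zero-length polyline, self-intersecting
    contour, empty region."""


class RegistrationError(MyoCapError):
    """Serial-section registration failed (too few fibres matched)."""


class ThinStructureWarning(UserWarning):
    """Rasterisation radius at or below the voxel size: thin structures may
    lose connectivity on the grid."""


class DegenerateChannelWarning(UserWarning):
    """A staining channel has no usable intensity separation; all fibres are
    called negative on it."""


class SingularFitWarning(UserWarning):
    """A mixed-model fit hit a boundary/singular covariance; estimates are
    returned but should be treated with care."""
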