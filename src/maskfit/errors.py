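"""Exception hierarchy shared across the package.

Two broad failure classes matter to callers (and to the CLI exit codes):
problems with the *input* (missing files, malformed meshes, degenerate
landmarks) and *numerical* failures (non-convergent fits, zero-variance
cohorts).
"""


class MaskfitError(Exception):
    """Base class for all package-specific failures."""


class InputError(MaskfitError, ValueError):
    """The supplied data is missing, malformed, or violates a precondition."""


class MeshError(InputError):
    """A triangle mesh is missing, malformed, or empty."""


class LandmarkError(InputError):
    """Landmarks are degenerate (coincident, collinear) or inconsistent."""


class ProfileError(MaskfitError):
    """Nasal-profile extraction failed (section misses the mesh, too few
    intersection points, no discernible ridge)."""


class NumericalError(MaskfitError):
    """A fit or statistic could not be computed (degenerate scale,
    solver breakdown)."""
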