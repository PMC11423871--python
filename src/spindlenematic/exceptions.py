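"""Exception hierarchy for the spindle-nematic analysis pipeline."""


class SpindleNematicError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(SpindleNematicError):
    """Geometric parameters do not define a valid shape (e.g. cap and convex
    arcs of a pole-indented tactoid fail to intersect, or a void sticks out
    of the spindle body)."""


class LowContrastError(SpindleNematicError):
    """Boundary extraction failed: too many polar bins without a gradient
    maximum above the noise floor."""


class FitFailureError(SpindleNematicError):
    """Model fit did not converge or the data are incompatible with the
    model (degenerate tactoid, non-converging sector assignment)."""


class DegenerateAverageError(SpindleNematicError):
    """Nematic mean undefined: the doubled-angle resultant is (numerically)
    zero, e.g. for {pi/4, 3pi/4}."""


class EmptyFrameError(SpindleNematicError):
    """Registration found no connected component above threshold."""


class SingularPointError(SpindleNematicError):
    """Field evaluated at a singular point (virtual pole or defect core)."""


class GridError(SpindleNematicError):
    """Grid does not have the symmetry required by the operation."""


class PackingInfeasibleError(SpindleNematicError):
    """Random or annealed placement exceeded the attempt budget."""


class GeometryInfeasibleError(SpindleNematicError):
    """No defect spacing reproduces the requested void width."""


class TracingError(SpindleNematicError):
    """Streamline tracing failed to close onto the target defect."""


class OverlapError(SpindleNematicError):
    """Void boundaries overlap at the requested separation."""


class OrientationUndefinedError(SpindleNematicError):
    """Plate orientation undefined (isotropic intensity distribution)."""


class EmptyPlateError(SpindleNematicError):
    """Chromosome segmentation produced zero components."""


class StepSizeError(SpindleNematicError):
    """Monte Carlo move sizes give zero acceptance at the initial
    temperature."""
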