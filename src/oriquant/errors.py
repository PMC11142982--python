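"""Exception hierarchy for oriquant.

Each failure mode the pipeline distinguishes gets its own class so callers
can react per stage (e.g. fall back to the sham-equivalent wedge when VAR
contrast separation fails).
"""


class OriQuantError(Exception):
    """Base class for all oriquant errors."""


class VolumeFormatError(OriQuantError):
    """A TIFF stack is malformed: mixed page shapes or dtypes."""


class NonGrayscaleError(VolumeFormatError):
    """A TIFF page carries more than one sample per pixel (not grayscale)."""


class SpectrumError(OriQuantError):
    """Invalid spectrum: non-monotone axis, negative intensity, bad band."""


class GeometryError(OriQuantError):
    """Phantom geometry is degenerate (e.g. the VAR wedge is empty)."""


class EmptyMaskError(OriQuantError):
    """An operation requiring a non-empty voxel mask received an empty one."""


class DegenerateDataError(OriQuantError):
    """Input data carry no usable contrast (constant volume, single bin...)."""


class SeparationError(OriQuantError):
    """No bimodal intensity separation found where one is required.

    Raised instead of guessing a threshold; the caller decides (for sham
    hearts the pipeline falls back to the equivalent-wedge rule).
    """


class ConvergenceError(OriQuantError):
    """A fit failed to converge after all restarts."""

    def __init__(self, message, best_residual=None):
        super().__init__(message)
        self.best_residual = best_residual
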