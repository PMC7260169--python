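"""Exception types raised across the processing chain."""


class ScaleTomoError(Exception):
    """Base class for all package-specific errors."""


class PolarityError(ScaleTomoError, ValueError):
    """A volume meant to be binary (material=0 / air=1) contains other values."""


class ShapeMismatchError(ScaleTomoError, ValueError):
    """Byte count, shape or axis extents are mutually inconsistent."""


class UnsupportedFormatError(ScaleTomoError, ValueError):
    """File extension or on-disk dtype outside the supported set."""


class ConfigurationError(ScaleTomoError, ValueError):
    """Physically inconsistent configuration (e.g. non-integral overlap frames)."""


class DegenerateStructureError(ScaleTomoError, ValueError):
    """Synthetic-structure parameters that cannot produce a two-phase network."""


class NoTextureError(ScaleTomoError, ValueError):
    """Registration was asked to match featureless (constant) frames."""


class TiltEstimationError(ScaleTomoError, ValueError):
    """No dominant object from which to estimate mounting tilt."""


class HaloTooSmallError(ScaleTomoError, ValueError):
    """Chunk halo smaller than the operator's spatial support radius."""


class StageError(ScaleTomoError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
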