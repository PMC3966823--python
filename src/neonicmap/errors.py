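"""Exception hierarchy shared across the pipeline stages."""


class NeonicmapError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NeonicmapError, ValueError):
    """A numeric argument violates its contract (negative, non-finite, ...)."""


class ConfigurationError(NeonicmapError):
    """Inconsistent configuration, e.g. a nodata code that is also a crop code."""


class IncompatibleRasterError(NeonicmapError):
    """Rasters differ in shape, resolution or year where they must agree."""


class OutOfRangeError(NeonicmapError):
    """A value falls outside the covered rate-category range."""


class DataFormatError(NeonicmapError):
    """A file could not be parsed; message names the file and location."""


class InvalidMeasurementError(NeonicmapError, ValueError):
    """A concentration measurement violates its contract (e.g. negative)."""


class InvalidSampleError(NeonicmapError):
    """A residue sample is internally inconsistent (e.g. mixed matrices)."""


class InvalidCategoryError(NeonicmapError):
    """An unknown crop or season label was encountered."""


class EmptyGroupError(NeonicmapError):
    """An operation was asked to summarize an empty group of samples."""


class EstimabilityError(NeonicmapError):
    """A fixed effect or contrast is not estimable; message names the terms."""


class DegenerateStructureError(NeonicmapError):
    """A random factor has too few levels to support a variance component."""


class ConvergenceError(NeonicmapError):
    """The mixed-model optimizer failed to converge within its restarts."""


class SelectionError(NeonicmapError):
    """Model selection had no convergent candidate to choose from."""
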