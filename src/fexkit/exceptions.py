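"""Exception hierarchy shared across fexkit."""


class FexKitError(Exception):
    """Base class for all fexkit-specific errors."""


class DegenerateGeometryError(FexKitError, ValueError):
    """Landmark geometry is unusable (coincident eye centers, collinear hull, ...)."""


class EmptyRegionError(FexKitError, ValueError):
    """A requested image region is empty after clipping to the image."""


class DegenerateDataError(FexKitError, ValueError):
    """Input data carries no usable variance."""


class CompatibilityError(FexKitError, ValueError):
    """Features were produced under a preprocessing configuration that does not
    match the fitted model."""


class UndefinedMetricError(FexKitError, ValueError):
    """The requested metric is undefined for these inputs (e.g. no ground truth)."""


class CollinearityError(FexKitError, ValueError):
    """A design/activation matrix is rank deficient; carries the offending columns."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConfigurationError(FexKitError, ValueError):
    """A recipe or configuration is internally inconsistent."""
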