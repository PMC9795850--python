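"""Exception hierarchy for the pipeline."""


class UavYieldError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UavYieldError):
    """Invalid design, parameter or method configuration."""


class RasterFormatError(UavYieldError):
    """Raster pair malformed or inconsistent (shape/band/transform mismatch)."""


class PlotClipError(UavYieldError):
    """A plot rectangle does not intersect the raster extent."""

    def __init__(self, plot_id: str, message: str | None = None):
        self.plot_id = plot_id
        super().__init__(message or f"plot {plot_id!r} does not intersect the raster extent")


class FeatureError(UavYieldError):
    """Feature extraction impossible on the given pixel block."""


class ScreeningError(UavYieldError):
    """Feature screening or outlier filtering cannot run as configured."""


class ModelError(UavYieldError):
    """Regression fitting/evaluation cannot run on the given data."""
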