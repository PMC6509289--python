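"""Exception hierarchy.

All package errors derive from :class:`SrtmKitError`; the CLI maps
:class:`ConfigError` to exit code 2 and :class:`DataError` (and subclasses)
to exit code 3.
"""


class SrtmKitError(Exception):
    """Base class for all srtmkit errors."""


class ConfigError(SrtmKitError):
    """Invalid or incomplete pipeline configuration."""


class DataError(SrtmKitError):
    """Invalid input data (files, arrays, tables)."""


class ScheduleError(DataError):
    """Frame schedules are invalid or do not match."""


class ParameterError(SrtmKitError):
    """A model or grid parameter is outside its valid domain."""


class SingularFitError(DataError):
    """The linear-stage design matrix is degenerate (e.g. zero reference)."""


class InsufficientDataError(DataError):
    """Fewer frames than model parameters."""


class ConvergenceError(SrtmKitError):
    """Nonlinear fit failed to converge; carries the final iterate."""

    def __init__(self, message, final_params=None):
        super().__init__(message)
        self.final_params = final_params


class EmptyRegionError(DataError):
    """A VOI or mask selects no voxels."""


class EmptySegmentationError(DataError):
    """No voxel satisfies the iso-contour threshold."""


class MissingBaselineError(DataError):
    """An animal lacks a baseline-day record for normalisation."""


class ZeroBaselineError(DataError):
    """Ratio normalisation against a zero baseline value."""


class DesignError(DataError):
    """Longitudinal design is not identifiable for the mixed model."""
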