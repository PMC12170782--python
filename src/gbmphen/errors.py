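"""Exception hierarchy shared by the pipeline stages."""


class GbmphenError(Exception):
    """Base class for all package errors."""


class FormatError(GbmphenError):
    """A file could not be parsed as the expected image container."""


class GridMismatchError(GbmphenError):
    """Two volumes do not share shape, voxel spacing and frame identity."""


class ParameterError(GbmphenError):
    """An acquisition or model parameter is out of its valid range."""


class NormalizationError(GbmphenError):
    """A normalization reference (e.g. a brain median) is degenerate."""


class FitError(GbmphenError):
    """A model fit could not be performed on the given data."""


class ClusteringError(GbmphenError):
    """Clustering was requested on degenerate input."""


class ConfigError(GbmphenError):
    """A configuration value is inconsistent or infeasible."""
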