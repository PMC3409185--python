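"""Exception hierarchy shared across the pipeline."""


class GammabeamError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(GammabeamError):
    """Sensor/head/grid geometry is inconsistent (e.g. shell inside head)."""


class ConfigurationError(GammabeamError):
    """A configuration value is invalid or produces an empty analysis."""


class SchemaError(GammabeamError):
    """A file does not conform to the documented container layout."""


class DegenerateStatisticError(GammabeamError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
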