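"""Exception hierarchy shared by all raredx modules."""


class RaredxError(Exception):
    """Base class for all raredx errors."""


class ConfigurationError(RaredxError):
    """Invalid configuration value (bad dimension, probability, threshold...)."""


class DataError(RaredxError):
    """Invalid or inconsistent input data (duplicate ids, dangling references...)."""


class InconsistencyError(DataError):
    """Internally contradictory data, e.g. cases recorded in an uninhabited unit."""


class FitError(RaredxError):
    """A regression could not be fit (too few points, degenerate predictor)."""


class SummaryError(RaredxError):
    """A summary was requested over an empty or unusable record set."""
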