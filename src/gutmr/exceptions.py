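"""Exception hierarchy shared across the pipeline stages."""


class GutMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GutMRError):
    """A user-supplied configuration (column map, threshold, weight table) is invalid."""


class InputError(GutMRError):
    """An input file or in-memory table violates its contract."""


class EstimationError(GutMRError):
    """An estimator cannot produce a result (undefined ratio, rank deficiency, non-convergence)."""
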