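"""Exception taxonomy shared across the pipeline.

The CLI maps these to exit codes: ConfigurationError -> 2, any other
ShapesKitError -> 1.
"""


class ShapesKitError(Exception):
    """Base class for all errors raised by shapes-kit."""


class ConfigurationError(ShapesKitError):
    """Invalid configuration value (bad probability, empty grid, missing file)."""


class DataError(ShapesKitError):
    """Malformed or inconsistent input data."""


class EvaluationError(DataError):
    """Structure-signal evaluation is impossible (e.g. one class empty)."""


class FitError(ShapesKitError):
    """Nonlinear fit failed to converge; carries the optimizer message."""
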