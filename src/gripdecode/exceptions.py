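"""Exception hierarchy shared across the pipeline."""


class GripDecodeError(Exception):
    """Base class for all package errors."""


class InputError(GripDecodeError, ValueError):
    """Malformed caller input (wrong shapes, out-of-range values)."""


class ConfigError(GripDecodeError, ValueError):
    """Invalid configuration (e.g. sampling rate too low for the bands)."""


class ParameterError(GripDecodeError, ValueError):
    """Invalid dynamic-model parameters (non-positive lag, negative delay)."""


class UnidentifiableError(GripDecodeError, RuntimeError):
    """Model cannot be identified from the data provided (e.g. zero features)."""


class DegenerateDataError(GripDecodeError, ArithmeticError):
    """Numerically degenerate data (zero baseline power, zero variance)."""
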