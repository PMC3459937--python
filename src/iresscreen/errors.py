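"""Exception hierarchy shared across the pipeline stages."""


class ScreenError(Exception):
    """Base class for all iresscreen errors."""


class WellParseError(ScreenError, ValueError):
    """A well coordinate could not be parsed (malformed or off-plate)."""


class IntegrityError(ScreenError, ValueError):
    """A tabular input violates its schema (duplicates, bad values)."""


class SizingError(ScreenError, ValueError):
    """Requested reactions do not fit the available plate capacity."""


class NormalizationError(ScreenError, ValueError):
    """A plate cannot be normalized (no usable scrambled controls)."""


class CalibrationError(ScreenError, ValueError):
    """Cut-off calibration failed (degenerate score distribution)."""


class EvaluationError(ScreenError, ValueError):
    """Secondary-screen evaluation failed (missing channel data)."""


class ParameterError(ScreenError, ValueError):
    """A statistical parameter is outside its valid domain."""
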