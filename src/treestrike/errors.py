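"""Exception types shared across the package."""


class TreestrikeError(Exception):
    """Base class for all treestrike errors."""


class InvalidInputError(TreestrikeError, ValueError):
    """A physical quantity was outside its valid domain."""


class InsufficientDataError(TreestrikeError, ValueError):
    """A fit was requested on data that cannot identify the model."""


class CalibrationError(TreestrikeError, ValueError):
    """A calibration step was given an empty or inconsistent reference."""
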