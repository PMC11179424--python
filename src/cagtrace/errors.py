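"""Exception hierarchy shared across the package."""


class CagTraceError(Exception):
    """Base class for all errors raised by cagtrace."""


class InputError(CagTraceError, ValueError):
    """Invalid argument values or inconsistent input data."""


class FormatError(CagTraceError, ValueError):
    """Malformed input file (missing columns, empty file, bad dialect)."""


class CalibrationError(CagTraceError, ValueError):
    """Size-to-repeat calibration cannot be established or is violated."""
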