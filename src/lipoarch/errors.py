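"""Exception hierarchy shared across the package."""


class LipoarchError(Exception):
    """Base class for package errors."""


class ParameterError(LipoarchError, ValueError):
    """A caller-supplied parameter is out of range or inconsistent."""


class DataError(LipoarchError, ValueError):
    """Input data violates a precondition (bad sequence, malformed table...)."""


class MotifParseError(DataError):
    """A degenerate motif pattern string could not be parsed."""
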