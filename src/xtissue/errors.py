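"""Exception types shared across the package."""


class XTissueError(Exception):
    """Base class for all package errors."""


class InputError(XTissueError, ValueError):
    """A caller-supplied value or table violates a precondition."""


class ConfigError(XTissueError, ValueError):
    """A configuration object is internally inconsistent."""


class ParseError(XTissueError, ValueError):
    """A file could not be parsed; message carries the line number."""
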