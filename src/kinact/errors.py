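"""Exception types shared across the package."""


class KinactError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(KinactError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ParseError(KinactError, ValueError):
    """A file could not be parsed; message names the file and location."""

    def __init__(self, path, message, line=None, column=None):
        loc = str(path)
        if line is not None:
            loc += f":{line}"
            if column is not None:
                loc += f":{column}"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line
        self.column = column


class DegenerateGeneError(KinactError, ValueError):
    """A gene has no usable expression values (all missing or max == 0)."""


class EmptyWindowError(KinactError, ValueError):
    """Label entropy was requested for an empty sample window."""
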