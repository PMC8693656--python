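"""Exception hierarchy with the pipeline's exit-code convention.

Exit codes: 0 success (including empty findings), 1 usage/config,
2 data/parse, 3 numeric/degenerate.
"""


class ProgmarkError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 3


class ConfigError(ProgmarkError):
    """Invalid configuration or usage (exit code 1)."""

    exit_code = 1


class ParseError(ProgmarkError):
    """Malformed on-disk input; message names file and line (exit code 2)."""

    exit_code = 2

    def __init__(self, message: str, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f"{path}: "
            if line is not None:
                loc = f"{path}:{line}: "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class DataError(ProgmarkError):
    """Semantically invalid data (exit code 2)."""

    exit_code = 2


class NumericError(ProgmarkError):
    """Degenerate numeric situation, e.g. an empty stratum (exit code 3)."""

    exit_code = 3
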