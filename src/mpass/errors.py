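"""Exception hierarchy.

``MpassError`` covers everything raised deliberately by this package.
``UserInputError`` marks problems with user-supplied data or options (CLI
exit code 1); anything else escaping to the CLI is treated as internal
(exit code 2).
"""


class MpassError(Exception):
    """Base class for errors raised by mpass."""


class UserInputError(MpassError):
    """Invalid user input: bad file, bad option value, mismatched labels."""


class ParseError(UserInputError):
    """Malformed input file.

    Parameters
    ----------
    message : str
    line : int, optional
        1-based line (or character position) where parsing failed.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
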