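"""Exception hierarchy shared across the package."""


class HexLogicError(Exception):
    """Base class for all errors raised by hexlogic."""


class ValidationError(HexLogicError):
    """A model, state or configuration violates a structural invariant."""


class ParseError(HexLogicError):
    """A textual input (rule, project file, SBML document) failed to parse."""

    def __init__(self, message: str, position: int | None = None, line: int | None = None):
        self.position = position
        self.line = line
        loc = ""
        if line is not None:
            loc = f" (line {line})"
        elif position is not None:
            loc = f" (at position {position})"
        super().__init__(message + loc)


class ConfigError(HexLogicError):
    """A simulation setting is out of its admissible range."""
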