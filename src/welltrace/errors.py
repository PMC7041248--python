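"""Exception hierarchy.

``ValidationError`` marks bad user input (CLI exit code 2); everything else
raised by the library is a plain exception or ``WelltraceError`` (exit 3).
"""


class WelltraceError(Exception):
    """Base class for errors raised by welltrace."""


class ValidationError(WelltraceError):
    """Invalid input or parameter value detected before any work is done."""


class LayoutError(ValidationError):
    """Inconsistent or malformed plate layout."""


class ParseError(ValidationError):
    """Malformed input file; the message names the offending line."""
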