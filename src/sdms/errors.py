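"""Exception hierarchy shared across the toolkit.

The CLI maps these onto distinct exit statuses so that batch pipelines can
tell a malformed input (validation) from a numerically degenerate one.
"""


class SdmsError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(SdmsError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A file or formula could not be parsed; the message names the spot."""


class DegeneracyError(SdmsError):
    """A computation is undefined for the given data (e.g. zero amplitude)."""
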