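"""Exception hierarchy shared by all stages.

Exit-code mapping used by the CLI: InputError -> 2, ConfigError -> 3,
anything else -> 1.
"""


class CpiDebiasError(Exception):
    """Base class for all package errors."""


class InputError(CpiDebiasError, ValueError):
    """A value or table violates a stage precondition."""


class ConfigError(CpiDebiasError, ValueError):
    """A configuration block is inconsistent or incomplete."""


class DegenerateInputError(InputError):
    """Input is structurally valid but carries no usable signal
    (constant matrix, single-class label vector, all-zero weights)."""
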