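"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: input problems exit 1, configuration
problems exit 2.
"""


class PodeegError(Exception):
    """Base class for all package errors."""


class ConfigError(PodeegError):
    """Invalid configuration value (bad quantile, band above Nyquist, ...)."""

    exit_code = 2


class InputError(PodeegError):
    """Unreadable or malformed input data (missing channels, NaNs, ...)."""

    exit_code = 1


class ContractError(PodeegError):
    """A caller violated a documented precondition."""


class DegenerateInputError(PodeegError):
    """Structurally valid input on which the operation is undefined
    (zero-variance channel, fully masked recording, every frame flagged)."""


class NumericalError(PodeegError):
    """An iterative numerical routine failed to converge."""
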