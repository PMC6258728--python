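"""Exception hierarchy shared across the package.

Every user-facing failure mode maps to one of these so that the CLI can
translate them into stable exit codes (config error 2, data error 3,
convergence error 4).
"""


class XimegaError(Exception):
    """Base class for all package errors."""


class ParameterError(XimegaError, ValueError):
    """Invalid parameter values (configuration problems)."""


class FormatError(XimegaError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(XimegaError, ValueError):
    """Structurally valid input on which the operation is undefined
    (e.g. all bins masked, constant matrix, empty list)."""


class MaskedBinError(XimegaError, ValueError):
    """A required bin is masked."""


class JoinError(XimegaError, ValueError):
    """Tables could not be matched on their key; carries offenders."""

    def __init__(self, message: str, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders) if offenders is not None else []


class ConvergenceError(XimegaError, RuntimeError):
    """Iterative solver failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
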