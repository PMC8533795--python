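"""Package exceptions.

``ValidationError`` maps to CLI exit code 2, ``ConvergenceError`` to 3.
"""


class NetGradientError(Exception):
    """Base class for package errors."""


class ValidationError(NetGradientError, ValueError):
    """Invalid inputs or configuration."""


class CoverageError(NetGradientError, KeyError):
    """A life-table stratum or cell required by the data is missing."""

    def __str__(self):  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class ConvergenceError(NetGradientError, RuntimeError):
    """Model fitting failed to converge."""
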