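"""Exception hierarchy.

All package errors derive from :class:`RadshapeError` so callers can catch
one type at the CLI boundary.  ``ValidationError`` marks bad user input
(exit code 1 at the CLI); everything else is a runtime failure (exit code 2).
"""


class RadshapeError(Exception):
    """Base class for all package errors."""


class ValidationError(RadshapeError, ValueError):
    """Invalid input data or parameters."""


class FormatError(RadshapeError):
    """Unreadable or malformed file content."""

    def __init__(self, path, message, line=None):
        self.path = str(path)
        self.line = line
        loc = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{loc}: {message}")


class IntegrityError(RadshapeError):
    """A stored archive is truncated, corrupt, or of the wrong type/version."""


class RegistrationError(RadshapeError):
    """Rigid registration failed (degenerate geometry or no accepted pairs)."""
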