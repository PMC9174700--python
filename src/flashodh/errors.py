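"""Exception types shared across the package."""


class FlashOdhError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FlashOdhError, ValueError):
    """Invalid parameter set or inconsistent configuration."""


class FitError(FlashOdhError, RuntimeError):
    """Nonlinear fit failed or produced a degenerate solution.

    Carries whatever diagnostics were available at the point of failure in
    ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RegistrationError(FlashOdhError, ValueError):
    """Voxel grids are not co-registered (shape or spacing mismatch)."""
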