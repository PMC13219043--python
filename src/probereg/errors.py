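"""Exception hierarchy shared across the package."""


class ProbeRegError(Exception):
    """Base class for all package-specific errors."""


class InvalidTransformError(ProbeRegError, ValueError):
    """A rotation matrix failed SO(3) validation or a transform is malformed."""


class FormatError(ProbeRegError, ValueError):
    """A file could not be parsed as the expected format."""


class PairingError(ProbeRegError, ValueError):
    """Landmark tables do not form complete source/target pairs."""


class ConfigError(ProbeRegError, ValueError):
    """A run configuration value is unknown or out of range."""


class ParameterError(ProbeRegError, ValueError):
    """An algorithm parameter is outside its documented valid range."""


class InsufficientLandmarksError(ProbeRegError, ValueError):
    """Fewer than three landmark pairs were supplied."""


class DegenerateGeometryError(ProbeRegError, ValueError):
    """Input geometry does not constrain the requested solve (collinear
    landmarks, rank-deficient normal equations, ...)."""


class LostRegistrationError(ProbeRegError, RuntimeError):
    """Every correspondence was gated out; the pose estimate is lost."""
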