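"""Exception types shared across the package."""


class BSFError(Exception):
    """Base class for all package-specific errors."""


class BoundaryError(BSFError, ValueError):
    """A reference-domain query lies outside the supported lattice region.

    Carries the offending coordinate so callers can report where the model
    was asked to extrapolate.
    """

    def __init__(self, coord, bounds):
        self.coord = coord
        self.bounds = bounds
        super().__init__(
            f"reference coordinate {coord} outside lattice support {bounds}"
        )


class ConfigurationError(BSFError, ValueError):
    """A required input (e.g. a displacement field for a frame pair) is missing."""


class FormatError(BSFError, ValueError):
    """An on-disk artefact does not satisfy the expected layout."""


class UnderdeterminedError(BSFError, ValueError):
    """A least-squares system has fewer equations than unknowns."""
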