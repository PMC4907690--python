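"""Exception types shared across the package."""


class PainsigError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PainsigError):
    """Volumes/masks with incompatible shape or affine were combined."""


class InvalidConfigError(PainsigError):
    """A configuration value violates its contract."""


class CoverageError(PainsigError):
    """Mask intersection covers too little of a pattern's weight mass."""

    def __init__(self, coverage: float, threshold: float):
        self.coverage = coverage
        self.threshold = threshold
        super().__init__(
            f"pattern coverage {coverage:.1%} below required {threshold:.0%}"
        )


class ZeroVarianceError(PainsigError):
    """A statistic is undefined because the input has no variance."""


class DegenerateDataError(PainsigError):
    """Input data are degenerate for the requested operation."""


class RankError(PainsigError):
    """A design matrix is rank deficient."""


class ValidationError(PainsigError):
    """A dataset failed structural validation."""
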