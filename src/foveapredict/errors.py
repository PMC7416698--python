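"""Exception types shared across the package."""


class FoveaPredictError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(FoveaPredictError):
    """Rendered retinal geometry puts two bands too close to resolve."""


class AlignmentError(FoveaPredictError):
    """A B-scan cannot be aligned (no detectable hyperreflective band)."""


class FoveolaNotFoundError(FoveaPredictError):
    """No pit depression found; caller should supply a manual override."""


class UnsegmentableScanError(FoveaPredictError):
    """Too few detectable bands to attempt layer segmentation."""


class ParseError(FoveaPredictError):
    """Malformed on-disk scan or table."""
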