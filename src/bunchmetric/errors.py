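"""Exception hierarchy.

Exit-code mapping for the CLI lives in :mod:`bunchmetric.cli`; library code
raises these and never calls ``sys.exit``.
"""


class BunchmetricError(Exception):
    """Base class for all package errors."""


class ArgumentError(BunchmetricError, ValueError):
    """Invalid argument value (bad count, non-positive edge, ...)."""


class ParseError(BunchmetricError):
    """Malformed point-cloud file; message names the offending byte/line."""


class EmptyCloudError(BunchmetricError):
    """An operation that requires points received none."""


class DegenerateGeometryError(BunchmetricError):
    """Rank-deficient covariance, coplanar hull input, and similar."""


class NotWatertightError(BunchmetricError):
    """Mesh volume requested on a mesh with boundary edges."""


class SegmentationError(BunchmetricError):
    """No cluster survived region growing."""


class RegistrationError(BunchmetricError):
    """ICP found no overlap, or a pairwise merge step failed."""


class AlphaTooSmallError(BunchmetricError):
    """Alpha-shape complex is empty at the requested alpha."""


class ReconstructionError(BunchmetricError):
    """Poisson isosurface extraction did not produce a watertight mesh."""


class GenerationError(BunchmetricError):
    """Synthetic bunch packing could not be satisfied."""


class FixtureError(BunchmetricError):
    """Packaged reference table failed its checksum."""
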