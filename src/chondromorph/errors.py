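"""Exception hierarchy for the chondromorph pipeline.

Every failure mode the pipeline can hit maps to a distinct exception class so
the CLI can translate them into stable exit codes.
"""


class ChondromorphError(Exception):
    """Base class for all chondromorph errors."""


class ConfigError(ChondromorphError):
    """Malformed or inconsistent configuration; message names the field path."""


class MissingInputError(ChondromorphError):
    """An expected input file, directory or slice stack does not exist."""


class FormatError(ChondromorphError):
    """Input files exist but are inconsistent (mixed shapes, bit depths...)."""


class BoundsError(ChondromorphError):
    """A voxel box or probe sphere does not fit inside its parent grid."""


class ParameterError(ChondromorphError):
    """Invalid operation parameters (e.g. min_voxels > max_voxels)."""


class DegenerateInputError(ChondromorphError):
    """A constant (zero-contrast) volume where contrast is required."""


class PlacementError(ChondromorphError):
    """Phantom object placement failed after bounded retries."""


class NoTissueError(ChondromorphError):
    """No slice of the volume passes the tissue-fraction threshold."""


class OutOfTissueError(ChondromorphError):
    """A centroid lies outside the detected tissue frame."""


class EmptyObjectError(ChondromorphError):
    """Morphometry requested on an empty mask."""


class UndefinedMetricError(ChondromorphError):
    """Metric undefined for the given inputs (e.g. Dice of two empty masks)."""


class UndefinedScoreError(ChondromorphError):
    """No probe radius fits the grid, so the interiority score is undefined."""


class VerificationReferenceError(ChondromorphError):
    """A manual-verification decision refers to an unknown record id."""


class VerificationConflictError(ChondromorphError):
    """Duplicate decisions for one record id with conflicting verdicts."""
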