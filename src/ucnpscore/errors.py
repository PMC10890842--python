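"""Exception hierarchy.

All package-specific failures derive from :class:`UCNPScoreError` so callers
(and the CLI, which maps them to exit code 3) can catch one type.
"""


class UCNPScoreError(Exception):
    """Base class for all errors raised by ucnpscore."""


class ShapeMismatchError(UCNPScoreError):
    """Two grids that must share geometry do not."""


class PixelSizeError(UCNPScoreError):
    """No physical pixel size could be resolved, or sizes disagree."""


class EmptyMaskError(UCNPScoreError):
    """The requested pass-band contains no discrete frequency bin."""


class CalibrationError(UCNPScoreError):
    """Level statistics cannot support threshold calibration."""


class DegenerateCriterionError(UCNPScoreError):
    """Band optimization criterion is undefined for every candidate."""


class ContrastError(UCNPScoreError):
    """Signal-to-background inputs violate their contracts."""


class PhantomError(UCNPScoreError):
    """Phantom specification cannot be realized."""
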