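"""Exception hierarchy.

Every failure mode named in the module contracts gets its own class so
callers (and the pipeline's per-patient isolation) can branch on type
rather than on message text.
"""


class SmritrackError(Exception):
    """Base class for all package errors."""


class GridMismatchError(SmritrackError):
    """Two volumes that must share a grid geometry do not."""


class VolumeFormatError(SmritrackError):
    """A file on disk is not a valid 3D volume of the expected kind
    (4D input, non-binary mask values, missing header spacing...)."""


class EmptyMaskError(SmritrackError):
    """An operation that requires a nonempty mask received an empty one."""


class CoverageError(SmritrackError):
    """Coverage intersection is empty or otherwise unusable."""


class PhantomConfigError(SmritrackError):
    """Invalid phantom configuration (e.g. tumor outside the brain)."""


class ReferenceRegionError(SmritrackError):
    """NAWM reference region too small or empty within coverage."""


class StatisticsError(SmritrackError):
    """Degenerate input to a statistical routine (constant sample,
    zero-variance differences, too few pairs...)."""


class ManifestError(SmritrackError):
    """Study manifest invalid or references missing files."""
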