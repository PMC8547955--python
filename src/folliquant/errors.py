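"""Exception hierarchy for pipeline-stage failures.

Input-validation problems (bad parameter values, malformed masks) raise
plain ``ValueError``; the classes here mark conditions that arise from the
*data* and that batch drivers are expected to catch and record per item.
"""


class FolliquantError(Exception):
    """Base class for data-driven analysis failures."""


class NoContactError(FolliquantError):
    """No persistent deflection rise above the baseline: no contact detected."""


class NoBaselineError(FolliquantError):
    """The sweep has no usable pre-contact region (all points in contact)."""


class InsufficientIndentationError(FolliquantError):
    """Fewer than the minimum number of in-contact points after conversion."""


class SparseWindowError(FolliquantError):
    """Too few force-indentation points inside the requested depth window."""


class NonPhysicalFitError(FolliquantError):
    """The windowed fit produced a non-positive stiffness slope."""


class EmptyCohortError(FolliquantError):
    """A cohort aggregation was requested on an empty fit list."""


class NoClusterError(FolliquantError):
    """A detection was requested with an empty cluster mask."""


class NoCompleteLifetimesError(FolliquantError):
    """Every track is censored; the mean lifetime is undefined."""


class FormatError(FolliquantError):
    """A file did not match the expected on-disk format; names the field."""
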