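"""Exception hierarchy with a stable exit-code contract for the CLI.

Exit codes: 0 ok, 2 input/format, 3 calibration, 4 segmentation,
5 empty wound, 6 statistics.
"""

from __future__ import annotations


class HsiWoundError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(HsiWoundError):
    """Malformed or contradictory file content (names the offending field)."""

    exit_code = 2


class DimensionError(HsiWoundError):
    """Array shapes or declared dimensions do not agree."""

    exit_code = 2


class ParameterError(HsiWoundError):
    """Invalid user-supplied parameter or configuration value."""

    exit_code = 2


class CalibrationError(HsiWoundError):
    """White-reference calibration cannot be performed."""

    exit_code = 3


class SegmentationError(HsiWoundError):
    """Clustering or wound-cluster selection failed."""

    exit_code = 4


class EmptyWoundError(HsiWoundError):
    """A wound mask with no pixels where one is required.

    Deliberately distinct from a measured area of zero: every study case had
    a visible wound, so an empty mask signals a segmentation failure the
    caller must confront rather than a tiny wound.
    """

    exit_code = 5

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class StatisticsError(HsiWoundError):
    """Undefined or degenerate statistic (zero variance, pe = 1, ...)."""

    exit_code = 6
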