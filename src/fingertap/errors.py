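"""Exception hierarchy shared across the pipeline.

All pipeline stages raise subclasses of :class:`FingertapError`, so callers
(notably :func:`fingertap.features.extract_all` and the CLI) can turn any
stage failure into an invalid-result record instead of a crash.
"""

from __future__ import annotations


class FingertapError(Exception):
    """Base class for all package errors."""


class FormatError(FingertapError):
    """Input table/file does not match the expected dialect."""


class EmptyTrackError(FingertapError):
    """No usable frames after parsing/validation."""


class EmptySignalError(FingertapError):
    """Fewer than two valid samples remain for signal construction."""


class SignalQualityError(FingertapError):
    """Too many frames had to be excluded (e.g. degenerate palm length)."""


class InsufficientCyclesError(FingertapError):
    """Fewer tapping cycles than the requested computation needs.

    Carries ``n_found`` so callers can report how many peaks/cycles were seen.
    """

    def __init__(self, message: str, n_found: int = 0):
        super().__init__(message)
        self.n_found = n_found


class ValidationError(FingertapError):
    """Out-of-domain value (e.g. a severity score outside 0-4)."""
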