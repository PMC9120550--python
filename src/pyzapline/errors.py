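"""Exception hierarchy.

Every error carries a short stable ``code`` string so that callers (CLI,
report JSON) can match on it without parsing messages.
"""

from __future__ import annotations


class ZaplineError(Exception):
    """Base class for all errors raised by this package."""

    code: str = "error"

    def __init__(self, message: str = ""):
        super().__init__(f"[{self.code}] {message}" if message else f"[{self.code}]")


class InvalidConfigError(ZaplineError):
    code = "invalid-config"


class RecordingTooShortError(ZaplineError):
    code = "recording-too-short"


class WindowTooLongError(ZaplineError):
    code = "window-too-long"


class WindowOutOfRangeError(ZaplineError):
    code = "window-out-of-range"


class EmptySearchRangeError(ZaplineError):
    code = "empty-search-range"


class ResolutionTooCoarseError(ZaplineError):
    code = "resolution-too-coarse"


class BandOutOfRangeError(ZaplineError):
    code = "band-out-of-range"


class TooFewEpochsError(ZaplineError):
    code = "too-few-epochs"


class FrequencyTooHighError(ZaplineError):
    code = "frequency-too-high"


class ChunkShorterThanNfftError(ZaplineError):
    code = "chunk-shorter-than-nfft"


class DegenerateCovarianceError(ZaplineError):
    code = "degenerate-covariance"


class NRemoveOutOfRangeError(ZaplineError):
    code = "nremove-out-of-range"


class EmptyScoresError(ZaplineError):
    code = "empty-scores"


class SpecOutOfBandError(ZaplineError):
    code = "spec-out-of-band"


class UnreadableFileError(ZaplineError):
    code = "unreadable-file"


class InconsistentChannelsError(ZaplineError):
    code = "inconsistent-channels"


class MissingSrateError(ZaplineError):
    code = "missing-srate"


class WriteFailedError(ZaplineError):
    code = "write-failed"


class RenderFailedError(ZaplineError):
    code = "render-failed"
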