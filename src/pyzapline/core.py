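"""Shared domain types, configuration defaults and unit conversions.

The central container is :class:`Recording` — a channels x samples matrix of
field amplitudes with its sampling rate.  :class:`CleaningConfig` holds every
tunable of the cleaning pipeline together with its documented default, and
round-trips through JSON so a finished run can be replicated exactly from the
emitted configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidConfigError, RecordingTooShortError

__all__ = [
    "Recording",
    "CleaningConfig",
    "db_to_power_ratio",
    "default_config",
    "validate_config",
]


@dataclass
class Recording:
    """A continuous multichannel recording.

    Parameters
    ----------
    data
        2-D array, channels x samples, arbitrary amplitude units.
    srate
        Sampling rate in Hz, > 0.
    channel_labels
        Optional channel names, one per row of ``data``.
    """

    data: np.ndarray
    srate: float
    channel_labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InvalidConfigError("recording data must be channels x samples (2-D)")
        if self.srate <= 0:
            raise InvalidConfigError(f"sampling rate must be positive, got {self.srate}")
        if self.channel_labels is not None:
            self.channel_labels = list(self.channel_labels)
            if len(self.channel_labels) != self.data.shape[0]:
                raise InvalidConfigError(
                    "channel_labels length does not match channel count"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.srate

    @property
    def nyquist(self) -> float:
        return self.srate / 2.0

    def validate(self) -> "Recording":
        """Check the structural invariants needed for spatial cleaning."""
        if self.n_channels < 2:
            raise InvalidConfigError(
                f"spatial filtering requires >= 2 channels, got {self.n_channels}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("recording contains non-finite values")
        return self

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(),
            self.srate,
            list(self.channel_labels) if self.channel_labels is not None else None,
        )


#: snake_case attribute -> external (JSON / CLI) spelling
CONFIG_FIELD_NAMES = {
    "noisefreqs": "noisefreqs",
    "minfreq": "minfreq",
    "maxfreq": "maxfreq",
    "adaptive_nremove": "adaptiveNremove",
    "fixed_nremove": "fixedNremove",
    "detection_winsize": "detectionWinsize",
    "coarse_freq_detect_power_diff": "coarseFreqDetectPowerDiff",
    "coarse_freq_detect_lower_power_diff": "coarseFreqDetectLowerPowerDiff",
    "search_individual_noise": "searchIndividualNoise",
    "freq_detect_mult_fine": "freqDetectMultFine",
    "detailed_freq_bounds_upper": "detailedFreqBoundsUpper",
    "detailed_freq_bounds_lower": "detailedFreqBoundsLower",
    "max_proportion_above_upper": "maxProportionAboveUpper",
    "max_proportion_below_lower": "maxProportionBelowLower",
    "noise_comp_detect_sigma": "noiseCompDetectSigma",
    "adaptive_sigma": "adaptiveSigma",
    "min_sigma": "minsigma",
    "max_sigma": "maxsigma",
    "chunk_length": "chunkLength",
    "min_chunk_length": "minChunkLength",
    "win_size_complete_spectrum": "winSizeCompleteSpectrum",
    "nkeep": "nkeep",
    "plot_results": "plotResults",
}


@dataclass
class CleaningConfig:
    """All tunables of the adaptive cleaning pipeline.

    Defaults are the recommended fully-automatic settings; in routine use none
    of them needs to be touched.  Frequencies are in Hz, spectral thresholds in
    10*log10 power units (dB), ``chunk_length``/``min_chunk_length`` in
    seconds, ``win_size_complete_spectrum`` in samples (0 = derive from the
    chunk length).
    """

    noisefreqs: Sequence[float] = field(default_factory=list)
    minfreq: float = 17.0
    maxfreq: float = 99.0
    adaptive_nremove: bool = True
    fixed_nremove: int = 1
    detection_winsize: float = 6.0
    coarse_freq_detect_power_diff: float = 4.0
    coarse_freq_detect_lower_power_diff: float = 1.76
    search_individual_noise: bool = True
    freq_detect_mult_fine: float = 2.0
    detailed_freq_bounds_upper: Sequence[float] = (-0.05, 0.05)
    detailed_freq_bounds_lower: Sequence[float] = (-0.4, 0.1)
    max_proportion_above_upper: float = 0.005
    max_proportion_below_lower: float = 0.005
    noise_comp_detect_sigma: float = 3.0
    adaptive_sigma: bool = True
    min_sigma: float = 2.5
    max_sigma: float = 4.0
    chunk_length: float = 0.0
    min_chunk_length: float = 30.0
    win_size_complete_spectrum: int = 0
    nkeep: int = 0
    plot_results: bool = True

    def __post_init__(self):
        self.noisefreqs = [float(f) for f in self.noisefreqs]
        self.detailed_freq_bounds_upper = tuple(
            float(x) for x in self.detailed_freq_bounds_upper
        )
        self.detailed_freq_bounds_lower = tuple(
            float(x) for x in self.detailed_freq_bounds_lower
        )

    def copy(self) -> "CleaningConfig":
        return CleaningConfig(**{f.name: getattr(self, f.name) for f in dataclasses.fields(self)})

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        """External-spelling dict suitable for the JSON config/report."""
        out = {}
        for attr, key in CONFIG_FIELD_NAMES.items():
            value = getattr(self, attr)
            if isinstance(value, tuple):
                value = list(value)
            out[key] = value
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CleaningConfig":
        reverse = {v: k for k, v in CONFIG_FIELD_NAMES.items()}
        kwargs = {}
        for key, value in d.items():
            if key not in reverse:
                raise InvalidConfigError(f"unknown config field {key!r}")
            kwargs[reverse[key]] = value
        return cls(**kwargs)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "CleaningConfig":
        return cls.from_dict(json.loads(s))


def db_to_power_ratio(delta: float) -> float:
    """Convert a 10*log10 power difference to a linear power ratio.

    A difference of 4 corresponds to an approximately 2.5-fold increase, a
    difference of 1.76 to an approximately 1.5-fold increase.
    """
    delta = float(delta)
    if not np.isfinite(delta):
        raise InvalidConfigError("delta must be finite")
    return float(10.0 ** (delta / 10.0))


def default_config() -> CleaningConfig:
    """The fully-automatic default configuration."""
    return CleaningConfig()


def validate_config(cfg: CleaningConfig, rec: Recording) -> CleaningConfig:
    """Check a configuration against a recording and fill auto values.

    Returns a normalized copy; the input is untouched.  The auto rule for
    ``win_size_complete_spectrum`` is ``srate * chunk_length`` when a fixed
    chunk length is set, else ``srate * min_chunk_length`` (long windows give
    the fine frequency resolution the peak detector needs).
    """
    rec.validate()
    cfg = cfg.copy()

    if cfg.minfreq >= cfg.maxfreq:
        raise InvalidConfigError(
            f"minfreq ({cfg.minfreq}) must be below maxfreq ({cfg.maxfreq})"
        )
    if cfg.detection_winsize <= 0:
        raise InvalidConfigError("detection_winsize must be positive")
    if cfg.fixed_nremove < 0:
        raise InvalidConfigError("fixed_nremove must be >= 0")
    if not (cfg.min_sigma <= cfg.noise_comp_detect_sigma <= cfg.max_sigma):
        raise InvalidConfigError(
            "noise_comp_detect_sigma must lie within [min_sigma, max_sigma]"
        )
    if cfg.chunk_length < 0:
        raise InvalidConfigError("chunk_length must be >= 0")
    if cfg.min_chunk_length <= 0:
        raise InvalidConfigError("min_chunk_length must be positive")
    if cfg.nkeep < 0:
        raise InvalidConfigError("nkeep must be >= 0")
    if cfg.max_proportion_above_upper < 0 or cfg.max_proportion_above_upper > 1:
        raise InvalidConfigError("max_proportion_above_upper must be in [0, 1]")
    if cfg.max_proportion_below_lower < 0 or cfg.max_proportion_below_lower > 1:
        raise InvalidConfigError("max_proportion_below_lower must be in [0, 1]")
    for name in ("detailed_freq_bounds_upper", "detailed_freq_bounds_lower"):
        lo, hi = getattr(cfg, name)
        if lo >= hi:
            raise InvalidConfigError(f"{name} must be an ascending interval")
    for f in cfg.noisefreqs:
        if not (0 < f < rec.nyquist):
            raise InvalidConfigError(f"noise frequency {f} Hz outside (0, Nyquist)")

    base_chunk = cfg.chunk_length if cfg.chunk_length > 0 else cfg.min_chunk_length
    if rec.n_samples < rec.srate * base_chunk:
        raise RecordingTooShortError(
            f"recording of {rec.duration:.1f} s cannot fit one {base_chunk:.0f} s chunk"
        )

    if cfg.win_size_complete_spectrum <= 0:
        cfg.win_size_complete_spectrum = int(round(rec.srate * base_chunk))
    cfg.win_size_complete_spectrum = int(
        min(cfg.win_size_complete_spectrum, rec.n_samples)
    )
    return cfg
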