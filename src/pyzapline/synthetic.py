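"""Ground-truthed synthetic recordings for testing and calibration.

The generator emulates the statistical structure the cleaning algorithm
assumes: a 1/f ("pink") multichannel background, plus one or more sinusoidal
noise sources of fixed or drifting frequency and amplitude, each projected
onto the channels through a spatial topography that may switch abruptly at
known change points (mimicking a participant moving or a device being
repositioned).  Noise amplitudes are calibrated against the background so
that the raw noise/surroundings power ratio matches a requested contamination
level — EEG-like ratios of roughly 2-7 up to MEG-like ratios of several
hundred.

Everything regenerates bit-identically from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import CleaningConfig, Recording
from .errors import SpecOutOfBandError
from .spectrum import center_power, welch_log_spectrum

__all__ = [
    "NoiseSourceSpec",
    "SyntheticTruth",
    "pink_background",
    "add_noise_sources",
    "measure_noise_ratio",
    "calibrate_amplitude",
    "standard_fixture",
    "standard_fixtures",
    "STANDARD_FIXTURE_NAMES",
]

Scalar = Union[float, int]
Trajectory = Union[Scalar, Tuple[Scalar, Scalar]]  # constant or linear ramp


@dataclass
class NoiseSourceSpec:
    """One oscillatory noise source.

    ``freq`` and ``amplitude`` may be a constant or a ``(start, end)`` pair
    realized as a linear ramp across the active interval.  ``topography``
    is one channel-weight vector, or a list of vectors (one more than
    ``topo_change_points``) switched at the stated times.
    """

    freq: Trajectory
    amplitude: Trajectory = 1.0
    topography: Union[np.ndarray, Sequence[np.ndarray], None] = None
    active_interval: Optional[Tuple[float, float]] = None  # seconds
    topo_change_points: Sequence[float] = field(default_factory=tuple)


@dataclass
class SyntheticTruth:
    """A generated recording with its exact decomposition."""

    clean: Recording
    noise: Recording
    combined: Recording
    specs: List[NoiseSourceSpec]
    seed: int


def pink_background(
    n_channels: int, duration_s: float, srate: float, seed: int
) -> Recording:
    """Independent 1/f Gaussian background per channel, exactly unit variance.

    Built by shaping white Gaussian noise in the frequency domain with a
    1/sqrt(f) amplitude profile (so the PSD falls off as 1/f), DC removed,
    then rescaling each channel to zero mean and unit sample variance.
    """
    n = int(round(duration_s * srate))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shape, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    x /= x.std(axis=-1, keepdims=True)
    return Recording(x, srate)


def _ramp(value: Trajectory, t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    if np.isscalar(value):
        return np.full_like(t, float(value))
    a, b = value
    frac = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    return float(a) + (float(b) - float(a)) * frac


def add_noise_sources(
    clean: Recording, specs: Sequence[NoiseSourceSpec], seed: int
) -> SyntheticTruth:
    """Project the noise sources onto the channels and add them to ``clean``.

    Each source is ``amplitude(t) * sin(2*pi*integral(freq) + phi)`` with the
    phase ``phi`` drawn once per source from the seeded generator, multiplied
    by its (possibly switching) topography.
    """
    rng = np.random.default_rng(seed)
    n_ch, n = clean.data.shape
    srate = clean.srate
    t = np.arange(n) / srate
    noise = np.zeros_like(clean.data)

    for spec in specs:
        t0, t1 = spec.active_interval if spec.active_interval else (0.0, n / srate)
        f_inst = _ramp(spec.freq, t, t0, t1)
        if np.any(f_inst <= 0) or np.any(f_inst >= srate / 2.0):
            raise SpecOutOfBandError(
                "instantaneous frequency leaves (0, Nyquist)"
            )
        amp = _ramp(spec.amplitude, t, t0, t1)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        phase = 2.0 * np.pi * np.cumsum(f_inst) / srate + phi
        s = amp * np.sin(phase)
        active = (t >= t0) & (t < t1)
        s = np.where(active, s, 0.0)

        topo = spec.topography
        if topo is None:
            topo = rng.standard_normal(n_ch)
        if isinstance(topo, np.ndarray) and topo.ndim == 1:
            topos = [topo]
        else:
            topos = [np.asarray(v, dtype=float) for v in topo]
        change_samples = [0] + [
            int(round(cp * srate)) for cp in spec.topo_change_points
        ] + [n]
        if len(topos) != len(change_samples) - 1:
            raise SpecOutOfBandError(
                "need one topography per segment between change points"
            )
        for w, a, b in zip(topos, change_samples[:-1], change_samples[1:]):
            w = np.asarray(w, dtype=float)
            if w.shape != (n_ch,) or not np.any(w):
                raise SpecOutOfBandError("topography must be a non-zero channel vector")
            noise[:, a:b] += np.outer(w, s[a:b])

    combined = Recording(clean.data + noise, srate, clean.channel_labels)
    return SyntheticTruth(
        clean=clean,
        noise=Recording(noise, srate, clean.channel_labels),
        combined=combined,
        specs=list(specs),
        seed=seed,
    )


def measure_noise_ratio(
    rec: Recording, f: float, cfg: Optional[CleaningConfig] = None
) -> float:
    """Noise/surroundings power ratio at ``f`` on the geometric-mean spectrum.

    Ratio of the mean power within +-0.05 Hz of ``f`` to the center power of
    the 6 Hz detection window; 1 means no peak.
    """
    cfg = cfg if cfg is not None else CleaningConfig()
    win = int(round(rec.srate * cfg.min_chunk_length))
    spec = welch_log_spectrum(rec, min(win, rec.n_samples))
    lo, hi = cfg.detailed_freq_bounds_upper
    idx = np.nonzero((spec.freqs >= f + lo) & (spec.freqs <= f + hi))[0]
    band = float(spec.mean_log_psd[idx].mean())
    center = center_power(spec.mean_log_psd, spec.freqs, f, cfg.detection_winsize)
    return float(10.0 ** ((band - center) / 10.0))


def calibrate_amplitude(
    clean: Recording,
    spec: NoiseSourceSpec,
    target_ratio: float,
    seed: int,
    n_refine: int = 1,
) -> float:
    """Amplitude scale giving a requested raw noise/surroundings ratio.

    Uses the fact that the excess ratio (ratio - 1) grows with the squared
    amplitude; starts from a probe amplitude and applies that power law, with
    a refinement iteration to absorb the mild nonlinearity of the
    geometric-mean spectrum.
    """
    base_amp = spec.amplitude
    f_mid = spec.freq if np.isscalar(spec.freq) else 0.5 * (spec.freq[0] + spec.freq[1])
    amp = 1.0
    for _ in range(n_refine + 1):
        probe = NoiseSourceSpec(
            freq=spec.freq,
            amplitude=_scale_traj(base_amp, amp),
            topography=spec.topography,
            active_interval=spec.active_interval,
            topo_change_points=spec.topo_change_points,
        )
        truth = add_noise_sources(clean, [probe], seed)
        r = measure_noise_ratio(truth.combined, float(f_mid))
        if r <= 1.0:
            amp *= 10.0
            continue
        amp *= float(np.sqrt((target_ratio - 1.0) / (r - 1.0)))
    return amp


def _scale_traj(value: Trajectory, scale: float) -> Trajectory:
    if np.isscalar(value):
        return float(value) * scale
    return (float(value[0]) * scale, float(value[1]) * scale)


STANDARD_FIXTURE_NAMES = (
    "stationary-50Hz",
    "drifting-peak",
    "switching-topography",
    "two-frequency",
    "meg-strong",
    "clean-only",
)


def standard_fixture(name: str, seed: int = 0) -> SyntheticTruth:
    """Deterministic named fixture; regenerates bit-identically from (name, seed).

    All fixtures are 300 s at 250 Hz.  The EEG-like fixtures use 24 channels
    and a raw noise/surroundings ratio around 7 (typical scalp-EEG
    contamination); "meg-strong" uses 64 channels and a ratio around 500
    (MEG-like).  "drifting-peak" drifts 49.95 -> 50.05 Hz,
    "switching-topography" switches its spatial pattern at 100 s and 200 s,
    and "two-frequency" adds a weaker 21 Hz source active only in the second
    half of the recording.
    """
    ss = np.random.SeedSequence(entropy=(seed, STANDARD_FIXTURE_NAMES.index(name)))
    bg_seed, src_seed, topo_seed = (int(s) % (2**31) for s in ss.generate_state(3))
    rng = np.random.default_rng(topo_seed)

    n_ch = 64 if name == "meg-strong" else 24
    clean = pink_background(n_ch, 300.0, 250.0, bg_seed)
    if name == "clean-only":
        return add_noise_sources(clean, [], src_seed)

    def topo():
        w = rng.standard_normal(n_ch)
        return w / np.linalg.norm(w)

    if name == "stationary-50Hz":
        specs = [NoiseSourceSpec(freq=50.0, topography=topo())]
        targets = [7.0]
    elif name == "drifting-peak":
        specs = [NoiseSourceSpec(freq=(49.95, 50.05), topography=topo())]
        targets = [7.0]
    elif name == "switching-topography":
        specs = [
            NoiseSourceSpec(
                freq=50.0,
                topography=[topo(), topo(), topo()],
                topo_change_points=(100.0, 200.0),
            )
        ]
        targets = [7.0]
    elif name == "two-frequency":
        specs = [
            NoiseSourceSpec(freq=50.0, topography=topo()),
            NoiseSourceSpec(
                freq=21.0, topography=topo(), active_interval=(150.0, 300.0)
            ),
        ]
        targets = [7.0, 4.0]
    elif name == "meg-strong":
        specs = [NoiseSourceSpec(freq=50.0, topography=topo())]
        targets = [500.0]
    else:
        raise ValueError(f"unknown fixture {name!r}")

    calibrated = []
    for spec, target in zip(specs, targets):
        amp = calibrate_amplitude(clean, spec, target, src_seed)
        calibrated.append(
            NoiseSourceSpec(
                freq=spec.freq,
                amplitude=_scale_traj(spec.amplitude, amp),
                topography=spec.topography,
                active_interval=spec.active_interval,
                topo_change_points=spec.topo_change_points,
            )
        )
    return add_noise_sources(clean, calibrated, src_seed)


def standard_fixtures(seed: int = 0) -> dict:
    """The complete named fixture catalog."""
    return {name: standard_fixture(name, seed) for name in STANDARD_FIXTURE_NAMES}
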