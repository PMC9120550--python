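"""Orchestration of the full adaptive cleaning loop.

For each detected (or user-given) noise frequency the driver:

1. segments the recording into chunks of stable noise topography;
2. cleans every chunk with the spectral-split + DSS operation, using the
   chunk's own fine-tuned peak frequency and an adaptively chosen number of
   removed components;
3. re-estimates the spectrum of the concatenated result and checks it for a
   remaining peak (cleaning too weak) or an introduced notch (too strong);
4. nudges the detection strength (sigma down / fixed minimum up when too
   weak, the opposite when too strong — with too strong taking precedence and
   latching, so the cleaning can never be strengthened again once it
   overshot) and re-runs the pass until no further adaptation is needed.

Subsequent noise frequencies are searched on the already-cleaned data
starting 0.05 Hz above the previous one.  The whole procedure is
deterministic: the same data and configuration reproduce the output bit for
bit, and the emitted ``final_config`` replays the run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core import CleaningConfig, Recording, validate_config
from .errors import BandOutOfRangeError
from .segmentation import ChunkPlan, plan_chunks
from .selector import iterative_outlier_count, resolve_nremove
from .spectrum import (
    SpectrumEstimate,
    chunk_log_spectrum,
    center_power,
    detect_chunk_peak,
    detect_next_noise_frequency,
    fine_threshold,
    welch_log_spectrum,
)
from .zapline import decompose_chunk, remove_components

__all__ = [
    "FrequencyLoopState",
    "CleaningVerdict",
    "ChunkRecord",
    "FrequencyRecord",
    "CleaningReport",
    "clean_frequency_pass",
    "evaluate_cleaning",
    "adapt_parameters",
    "compute_analytics",
    "run",
]

#: hard cap on adaptation re-runs per frequency; the bounded sigma / fixed
#: lattice converges well before, this only guards pathological oscillation
MAX_ADAPTATION_PASSES = 10

#: offset added to a finished noise frequency before searching for the next
NEXT_FREQ_OFFSET = 0.05


@dataclass
class FrequencyLoopState:
    """Mutable adaptation state while cleaning one noise frequency."""

    f_target: float
    sigma: float
    fixed_nremove: int
    was_too_strong: bool = False
    iteration: int = 0


@dataclass
class CleaningVerdict:
    """Outcome of the post-cleaning spectrum check."""

    too_weak: bool
    too_strong: bool
    proportion_above: float
    proportion_below: float


@dataclass
class ChunkRecord:
    """Per-chunk analytics for one noise frequency."""

    start: int
    stop: int
    n_removed: int
    scores: np.ndarray
    peak_frequency: float
    noise_present: bool


@dataclass
class FrequencyRecord:
    """Everything recorded about the cleaning of one noise frequency."""

    frequency: float
    sigma_used: float
    fixed_nremove_used: int
    n_adaptation_passes: int
    chunk_records: List[ChunkRecord]
    proportion_removed_power_full: float
    proportion_removed_power_noise_band: float
    proportion_removed_power_below_noise: float
    ratio_noise_to_surroundings_raw: float
    ratio_noise_to_surroundings_clean: float
    proportion_above_upper: float
    proportion_below_lower: float
    removed_mean_log_psd: np.ndarray
    clean_mean_log_psd: np.ndarray

    @property
    def n_removed_per_chunk(self) -> np.ndarray:
        return np.array([c.n_removed for c in self.chunk_records])

    @property
    def chunk_peak_frequencies(self) -> np.ndarray:
        return np.array([c.peak_frequency for c in self.chunk_records])

    @property
    def noise_present_flags(self) -> np.ndarray:
        return np.array([c.noise_present for c in self.chunk_records])

    def scores_matrix(self) -> np.ndarray:
        """chunks x components matrix of artifact scores, NaN-padded."""
        width = max(c.scores.size for c in self.chunk_records)
        out = np.full((len(self.chunk_records), width), np.nan)
        for i, c in enumerate(self.chunk_records):
            out[i, : c.scores.size] = c.scores
        return out


@dataclass
class CleaningReport:
    """Complete analytics of one cleaning run."""

    final_config: CleaningConfig
    raw_log_spectrum: SpectrumEstimate
    clean_log_spectrum: SpectrumEstimate
    frequencies: List[FrequencyRecord] = field(default_factory=list)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        """JSON-ready dict (schema-versioned) with every analytics field."""

        def _round(a):
            return np.round(np.asarray(a, dtype=float), 4).tolist()

        return {
            "schema_version": 1,
            "seed": self.seed,
            "final_config": self.final_config.to_dict(),
            "raw_log_spectrum": {
                "freqs": _round(self.raw_log_spectrum.freqs),
                "log_psd": _round(self.raw_log_spectrum.log_psd),
                "mean_log_psd": _round(self.raw_log_spectrum.mean_log_psd),
            },
            "clean_log_spectrum": {
                "freqs": _round(self.clean_log_spectrum.freqs),
                "log_psd": _round(self.clean_log_spectrum.log_psd),
                "mean_log_psd": _round(self.clean_log_spectrum.mean_log_psd),
            },
            "frequencies": [
                {
                    "frequency": f.frequency,
                    "sigma_used": f.sigma_used,
                    "fixed_nremove_used": f.fixed_nremove_used,
                    "n_adaptation_passes": f.n_adaptation_passes,
                    "proportion_removed_power_full": f.proportion_removed_power_full,
                    "proportion_removed_power_noise_band": f.proportion_removed_power_noise_band,
                    "proportion_removed_power_below_noise": f.proportion_removed_power_below_noise,
                    "ratio_noise_to_surroundings_raw": f.ratio_noise_to_surroundings_raw,
                    "ratio_noise_to_surroundings_clean": f.ratio_noise_to_surroundings_clean,
                    "proportion_above_upper": f.proportion_above_upper,
                    "proportion_below_lower": f.proportion_below_lower,
                    "chunk_boundaries": [
                        [c.start, c.stop] for c in f.chunk_records
                    ],
                    "n_removed_per_chunk": f.n_removed_per_chunk.tolist(),
                    "chunk_peak_frequencies": _round(f.chunk_peak_frequencies),
                    "noise_present_per_chunk": [
                        bool(x) for x in f.noise_present_flags
                    ],
                    "artifact_scores": _round(
                        np.nan_to_num(f.scores_matrix(), nan=-1.0)
                    ),
                }
                for f in self.frequencies
            ],
        }


def clean_frequency_pass(
    rec: Recording,
    f_target: float,
    plan: ChunkPlan,
    state: FrequencyLoopState,
    cfg: CleaningConfig,
) -> Tuple[Recording, List[ChunkRecord]]:
    """One cleaning pass over all chunks at the current adaptation state.

    Each chunk is cleaned at its own fine-tuned peak frequency when
    ``search_individual_noise`` is on and the artifact is present there;
    chunks without a detectable artifact are cleaned at the global target
    frequency with only the fixed minimum number of components removed.
    """
    cleaned = np.empty_like(rec.data)
    records: List[ChunkRecord] = []
    for start, stop in plan:
        chunk = Recording(rec.data[:, start:stop], rec.srate, rec.channel_labels)
        if cfg.search_individual_noise:
            f_chunk, present = detect_chunk_peak(
                chunk_log_spectrum(chunk), f_target, cfg
            )
        else:
            f_chunk, present = f_target, True
        f_use = f_chunk if present else f_target

        smoothed, residual, dss = decompose_chunk(chunk, f_use, cfg)
        if present and cfg.adaptive_nremove:
            n_out = iterative_outlier_count(dss.scores, state.sigma)
        else:
            n_out = 0
        n_remove = resolve_nremove(
            n_out, state.fixed_nremove, dss.n_effective, present, cfg.adaptive_nremove
        )
        if n_remove == 0:  # removing nothing is the exact identity
            cleaned[:, start:stop] = chunk.data
        else:
            denoised = remove_components(residual, dss, n_remove)
            cleaned[:, start:stop] = smoothed.data + denoised.data
        records.append(
            ChunkRecord(start, stop, n_remove, dss.scores, f_use, present)
        )
    return Recording(cleaned, rec.srate, rec.channel_labels), records


def evaluate_cleaning(
    clean_spec: SpectrumEstimate, f_target: float, cfg: CleaningConfig
) -> CleaningVerdict:
    """Check the cleaned spectrum for a residual peak or an introduced notch.

    Too weak: more than ``max_proportion_above_upper`` of the bins within
    +-0.05 Hz of the target lie above the fine threshold's upper bound.
    Too strong: more than ``max_proportion_below_lower`` of the bins within
    [-0.4, +0.1] Hz lie below the lower bound (a notch from overcleaning
    typically sits slightly below the noise frequency, hence the asymmetry).
    """
    thr = fine_threshold(clean_spec.mean_log_psd, clean_spec.freqs, f_target, cfg)
    curve = clean_spec.mean_log_psd

    def band_bins(bounds):
        lo, hi = bounds
        idx = np.nonzero(
            (clean_spec.freqs >= f_target + lo) & (clean_spec.freqs <= f_target + hi)
        )[0]
        if idx.size == 0:
            raise BandOutOfRangeError(
                f"no spectrum bins in [{f_target + lo}, {f_target + hi}] Hz"
            )
        return idx

    upper_idx = band_bins(cfg.detailed_freq_bounds_upper)
    lower_idx = band_bins(cfg.detailed_freq_bounds_lower)
    prop_above = float(np.mean(curve[upper_idx] > thr.upper))
    prop_below = float(np.mean(curve[lower_idx] < thr.lower))
    return CleaningVerdict(
        too_weak=prop_above > cfg.max_proportion_above_upper,
        too_strong=prop_below > cfg.max_proportion_below_lower,
        proportion_above=prop_above,
        proportion_below=prop_below,
    )


def adapt_parameters(
    verdict: CleaningVerdict, state: FrequencyLoopState, cfg: CleaningConfig
) -> Tuple[FrequencyLoopState, bool]:
    """Update the adaptation state from a verdict; return (state, continue).

    Too strong takes precedence over too weak, and latches: once the cleaning
    overshot, it can never be strengthened again.  The sigma ladder moves in
    0.25 steps within [min_sigma, max_sigma]; the fixed removal count never
    drops below its configured initial value.
    """
    if not cfg.adaptive_sigma:
        return state, False

    new = FrequencyLoopState(
        state.f_target,
        state.sigma,
        state.fixed_nremove,
        state.was_too_strong,
        state.iteration + 1,
    )
    if verdict.too_strong:
        new.sigma = min(state.sigma + 0.25, cfg.max_sigma)
        new.fixed_nremove = max(state.fixed_nremove - 1, cfg.fixed_nremove)
        new.was_too_strong = True
    elif verdict.too_weak:
        if state.was_too_strong:
            return new, False  # never strengthen again after an overshoot
        new.sigma = max(state.sigma - 0.25, cfg.min_sigma)
        new.fixed_nremove = state.fixed_nremove + 1
    else:
        return new, False  # converged

    changed = (
        new.sigma != state.sigma or new.fixed_nremove != state.fixed_nremove
    )
    return new, changed and new.iteration < MAX_ADAPTATION_PASSES


def _band_mean(spec: SpectrumEstimate, lo: float, hi: float) -> float:
    idx = np.nonzero((spec.freqs >= lo) & (spec.freqs <= hi))[0]
    if idx.size == 0:
        raise BandOutOfRangeError(f"no spectrum bins in [{lo}, {hi}] Hz")
    return float(spec.mean_log_psd[idx].mean())


def compute_analytics(
    raw_spec: SpectrumEstimate,
    clean_spec: SpectrumEstimate,
    f: float,
    cfg: CleaningConfig,
) -> dict:
    """Removed-power proportions and noise/surroundings ratios for one frequency.

    All quantities are computed on the log-mean (geometric-mean) spectra.  A
    removed-power proportion over a band is ``1 - 10**((clean - raw)/10)``
    with band-averaged log powers; the noise/surroundings ratio is the linear
    ratio of the +-0.05 Hz band power to the center power of the 6 Hz
    detection window, so a ratio of 1 means no residual peak.
    """
    lo, hi = cfg.detailed_freq_bounds_upper
    f_lo, f_hi = f + lo, f + hi
    full_lo, full_hi = raw_spec.freqs[0], raw_spec.freqs[-1]
    # below-noise band clamped to the spectrum's range
    below_lo, below_hi = max(f - 11.0, full_lo), f - 1.0

    def removed(lo_, hi_):
        delta = _band_mean(clean_spec, lo_, hi_) - _band_mean(raw_spec, lo_, hi_)
        return 1.0 - 10.0 ** (delta / 10.0)

    def ratio(spec):
        band = _band_mean(spec, f_lo, f_hi)
        center = center_power(spec.mean_log_psd, spec.freqs, f, cfg.detection_winsize)
        return 10.0 ** ((band - center) / 10.0)

    return {
        "proportion_removed_power_full": removed(full_lo, full_hi),
        "proportion_removed_power_noise_band": removed(f_lo, f_hi),
        "proportion_removed_power_below_noise": removed(below_lo, below_hi),
        "ratio_noise_to_surroundings_raw": ratio(raw_spec),
        "ratio_noise_to_surroundings_clean": ratio(clean_spec),
    }


def _clean_one_frequency(
    data: Recording, f: float, cfg: CleaningConfig
) -> Tuple[Recording, FrequencyRecord]:
    """Adaptive cleaning of a single noise frequency on the current data."""
    pre_spec = welch_log_spectrum(data, cfg.win_size_complete_spectrum)
    plan = plan_chunks(data, f, cfg)
    state = FrequencyLoopState(f, cfg.noise_comp_detect_sigma, cfg.fixed_nremove)

    while True:
        cleaned, records = clean_frequency_pass(data, f, plan, state, cfg)
        clean_spec = welch_log_spectrum(cleaned, cfg.win_size_complete_spectrum)
        verdict = evaluate_cleaning(clean_spec, f, cfg)
        state, keep_going = adapt_parameters(verdict, state, cfg)
        if not keep_going:
            break

    removed = Recording(data.data - cleaned.data, data.srate, data.channel_labels)
    removed_spec = welch_log_spectrum(removed, cfg.win_size_complete_spectrum)
    analytics = compute_analytics(pre_spec, clean_spec, f, cfg)
    record = FrequencyRecord(
        frequency=f,
        sigma_used=state.sigma,
        fixed_nremove_used=state.fixed_nremove,
        n_adaptation_passes=state.iteration,
        chunk_records=records,
        proportion_above_upper=verdict.proportion_above,
        proportion_below_lower=verdict.proportion_below,
        removed_mean_log_psd=removed_spec.mean_log_psd,
        clean_mean_log_psd=clean_spec.mean_log_psd,
        **analytics,
    )
    return cleaned, record


def run(
    rec: Recording,
    cfg: Optional[CleaningConfig] = None,
    seed: Optional[int] = None,
) -> Tuple[Recording, CleaningReport]:
    """Clean a recording of every detected frequency-specific noise artifact.

    When ``cfg.noisefreqs`` is empty, outlier frequencies are detected
    automatically between ``minfreq`` and ``maxfreq``, each detection running
    on the spectrum of the data already cleaned of previous frequencies;
    otherwise the given frequencies are cleaned verbatim (chunk-level peak
    fine-tuning still applies).  Returns the cleaned recording and the full
    report; re-running with ``report.final_config`` on the same raw data
    reproduces the output bit-identically — the whole pipeline is
    deterministic, ``seed`` is only recorded for provenance.
    """
    cfg = validate_config(cfg if cfg is not None else CleaningConfig(), rec)
    raw_spec = welch_log_spectrum(rec, cfg.win_size_complete_spectrum)

    data = rec.copy()
    records: List[FrequencyRecord] = []

    if cfg.noisefreqs:
        for f in cfg.noisefreqs:
            data, record = _clean_one_frequency(data, float(f), cfg)
            records.append(record)
    else:
        search_min = cfg.minfreq
        while search_min < cfg.maxfreq:
            spec_now = welch_log_spectrum(data, cfg.win_size_complete_spectrum)
            f = detect_next_noise_frequency(spec_now, search_min, cfg.maxfreq, cfg)
            if f is None:
                break
            data, record = _clean_one_frequency(data, f, cfg)
            records.append(record)
            search_min = f + NEXT_FREQ_OFFSET

    clean_spec = welch_log_spectrum(data, cfg.win_size_complete_spectrum)
    final_config = cfg.copy()
    final_config.noisefreqs = [r.frequency for r in records]
    report = CleaningReport(
        final_config=final_config,
        raw_log_spectrum=raw_spec,
        clean_log_spectrum=clean_spec,
        frequencies=records,
        seed=seed,
    )
    return data, report
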