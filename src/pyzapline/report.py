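"""Per-frequency diagnostic figure.

One figure per cleaned noise frequency, eight panels in two rows: the top
row documents the cleaning process (zoomed raw spectrum with the detection
threshold, removed components per chunk, per-chunk peak frequencies, mean
component scores with the mean removal line, zoomed cleaned spectrum with
the adaptation thresholds), the bottom row the outcome (full raw spectrum
with the search range shaded, cleaned versus removed spectra on an axis
relative to the noise frequency, and the spectra over the 10 Hz below the
noise frequency with the analytics in the title).  When the adaptation loop
re-runs, the figure for that frequency is simply overwritten, so only the
final state is ever on disk.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .core import CleaningConfig
from .driver import FrequencyRecord
from .errors import RenderFailedError
from .spectrum import SpectrumEstimate, center_power, fine_threshold

__all__ = ["build_frequency_figure", "render_frequency_figure"]

# Okabe-Ito colorblind-friendly palette
_RAW = "#000000"
_CLEAN = "#009E73"
_REMOVED = "#D55E00"
_THRESH = "#CC79A7"
_SHADE = "#56B4E9"


def render_frequency_figure(
    record: FrequencyRecord,
    raw_spec: SpectrumEstimate,
    cfg: CleaningConfig,
    outpath,
) -> Path:
    """Render the eight-panel diagnostic figure for one noise frequency.

    Writes (overwriting) ``outpath`` and returns it.
    """
    try:
        fig = build_frequency_figure(record, raw_spec, cfg)
        fig.savefig(outpath, dpi=110)
        plt.close(fig)
        return Path(outpath)
    except Exception as exc:
        raise RenderFailedError(f"figure for {record.frequency} Hz: {exc}") from exc


def _zoom(freqs: np.ndarray, f: float, half: float) -> np.ndarray:
    return np.nonzero((freqs >= f - half) & (freqs <= f + half))[0]


def build_frequency_figure(
    record: FrequencyRecord,
    raw_spec: SpectrumEstimate,
    cfg: CleaningConfig,
):
    """Build (but do not save) the eight-panel figure; returns the Figure."""
    f = record.frequency
    freqs = raw_spec.freqs
    raw_curve = raw_spec.mean_log_psd
    clean_curve = record.clean_mean_log_psd
    removed_curve = record.removed_mean_log_psd

    fig, axes = plt.subplots(2, 4, figsize=(18, 8))
    (ax_a, ax_b, ax_c, ax_d), (ax_e, ax_f, ax_g, ax_h) = axes

    # (a) zoomed raw spectrum with coarse detection threshold
    z = _zoom(freqs, f, 1.1)
    ax_a.plot(freqs[z], raw_curve[z], color=_RAW)
    cp = center_power(raw_curve, freqs, f, cfg.detection_winsize)
    ax_a.axhline(
        cp + cfg.coarse_freq_detect_power_diff, color=_THRESH, label="detection threshold"
    )
    ax_a.set_title(f"raw spectrum around {f:.2f} Hz")
    ax_a.set_xlabel("frequency (Hz)")
    ax_a.set_ylabel("power (10*log10 PSD)")
    ax_a.legend(fontsize=8)

    # (b) removed components per chunk
    n_rm = record.n_removed_per_chunk
    ax_b.bar(np.arange(n_rm.size), n_rm, color=_CLEAN)
    ax_b.set_title(f"removed components per chunk (mean {n_rm.mean():.2f})")
    ax_b.set_xlabel("chunk")
    ax_b.set_ylabel("# removed")

    # (c) chunk peak frequencies, noise-absent chunks marked
    peaks = record.chunk_peak_frequencies
    present = record.noise_present_flags
    x = np.arange(peaks.size)
    ax_c.plot(x[present], peaks[present], "o", color=_CLEAN, label="noise found")
    if np.any(~present):
        ax_c.plot(x[~present], peaks[~present], "x", color=_REMOVED, label="no noise")
    ax_c.set_title("chunk noise peak frequencies")
    ax_c.set_xlabel("chunk")
    ax_c.set_ylabel("frequency (Hz)")
    ax_c.legend(fontsize=8)

    # (d) mean artifact scores, abscissa cut to one third of the components
    scores = record.scores_matrix()
    mean_scores = np.nanmean(scores, axis=0)
    ax_d.plot(np.arange(1, mean_scores.size + 1), mean_scores, color=_RAW)
    ax_d.axvline(max(n_rm.mean(), 1e-9), color=_THRESH, label="mean # removed")
    ax_d.set_xlim(0.5, max(mean_scores.size / 3.0, 1.5))
    ax_d.set_title(f"mean artifact scores (sigma = {record.sigma_used:.2f})")
    ax_d.set_xlabel("component")
    ax_d.set_ylabel("score")
    ax_d.legend(fontsize=8)

    # (e) zoomed cleaned spectrum with adaptation thresholds, y shared with (a)
    thr = fine_threshold(clean_curve, freqs, f, cfg)
    ax_e.plot(freqs[z], clean_curve[z], color=_CLEAN)
    ax_e.axhline(thr.upper, color=_THRESH, linestyle="--", label="upper threshold")
    ax_e.axhline(thr.lower, color=_THRESH, linestyle=":", label="lower threshold")
    ax_e.set_ylim(ax_a.get_ylim())
    ax_e.set_title(
        f"cleaned ({record.proportion_above_upper * 100:.1f}% above, "
        f"{record.proportion_below_lower * 100:.1f}% below)"
    )
    ax_e.set_xlabel("frequency (Hz)")
    ax_e.set_ylabel("power (10*log10 PSD)")
    ax_e.legend(fontsize=8)

    # (f) full raw spectrum with the search range shaded
    ax_f.plot(freqs, raw_curve, color=_RAW)
    ax_f.axvspan(cfg.minfreq, cfg.maxfreq, color=_SHADE, alpha=0.2, label="search range")
    ax_f.set_title("full raw spectrum")
    ax_f.set_xlabel("frequency (Hz)")
    ax_f.set_ylabel("power (10*log10 PSD)")
    ax_f.legend(fontsize=8)

    # (g) clean and removed spectra, frequency axis relative to the noise frequency
    rel = freqs / f
    ax_g.plot(rel, clean_curve, color=_CLEAN, label="clean")
    ax_g.plot(rel, removed_curve, color=_REMOVED, label="removed")
    ax_g.set_title("clean vs removed (relative frequency)")
    ax_g.set_xlabel("frequency / noise frequency")
    ax_g.set_ylabel("power (10*log10 PSD)")
    ax_g.legend(fontsize=8)

    # (h) raw vs clean over the 10 Hz below the noise frequency, analytics in title
    zb = _zoom(freqs, f - 6.0, 5.0)  # [f-11, f-1]
    ax_h.plot(freqs[zb], raw_curve[zb], color=_RAW, label="raw")
    ax_h.plot(freqs[zb], clean_curve[zb], color=_CLEAN, label="clean")
    ax_h.set_title(
        f"below noise | removed: full {record.proportion_removed_power_full * 100:.2f}%, "
        f"band {record.proportion_removed_power_noise_band * 100:.1f}%, "
        f"below {record.proportion_removed_power_below_noise * 100:.2f}% | "
        f"ratio {record.ratio_noise_to_surroundings_raw:.2f} -> "
        f"{record.ratio_noise_to_surroundings_clean:.2f}",
        fontsize=8,
    )
    ax_h.set_xlabel("frequency (Hz)")
    ax_h.set_ylabel("power (10*log10 PSD)")
    ax_h.legend(fontsize=8)

    fig.suptitle(f"noise frequency {f:.2f} Hz")
    fig.tight_layout()
    return fig
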