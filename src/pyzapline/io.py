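"""Reading and writing recordings and cleaning reports.

Three on-disk carriers are supported:

* ``edf``            — European Data Format; read through :mod:`mne`, written
                       by a minimal single-record EDF writer (16-bit samples,
                       so round trips are exact only up to quantization);
* ``binary-float``   — little-endian float64, channel-major, with a small
                       JSON sidecar (``<path>.json``) holding shape, sampling
                       rate and labels; the exact fixture carrier;
* ``delimited-text`` — one sample per row, one channel per column (or the
                       transpose, per the declared orientation).

The cleaning report is serialized as schema-versioned JSON from which the
exact configuration can be reloaded to replay a run.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np

from .core import CleaningConfig, Recording
from .driver import CleaningReport
from .errors import (
    InconsistentChannelsError,
    MissingSrateError,
    UnreadableFileError,
    WriteFailedError,
)

__all__ = [
    "RecordingFileSpec",
    "read_recording",
    "write_recording",
    "write_outputs",
    "load_report_config",
]

FORMATS = ("edf", "binary-float", "delimited-text")


@dataclass
class RecordingFileSpec:
    """Where and how a recording lives on disk."""

    path: str
    format: str  # "edf" | "binary-float" | "delimited-text"
    orientation: str = "channels-by-samples"
    srate: Optional[float] = None  # override / required for headerless formats

    def __post_init__(self):
        if self.format not in FORMATS:
            raise UnreadableFileError(f"unknown format {self.format!r}")
        if self.orientation not in ("channels-by-samples", "samples-by-channels"):
            raise UnreadableFileError(f"unknown orientation {self.orientation!r}")


def read_recording(spec: RecordingFileSpec) -> Recording:
    """Read a recording into the canonical channels x samples orientation."""
    path = Path(spec.path)
    if not path.exists():
        raise UnreadableFileError(f"{path} does not exist")
    if spec.format == "edf":
        return _read_edf(path, spec)
    if spec.format == "binary-float":
        return _read_binary(path, spec)
    return _read_text(path, spec)


def _read_edf(path: Path, spec: RecordingFileSpec) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted exception types
        raise UnreadableFileError(f"failed to parse EDF {path}: {exc}") from exc
    srate = spec.srate if spec.srate else float(raw.info["sfreq"])
    return Recording(raw.get_data(), srate, list(raw.ch_names))


def _read_binary(path: Path, spec: RecordingFileSpec) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    srate = spec.srate or meta.get("srate")
    if not srate:
        raise MissingSrateError(f"no sampling rate for headerless file {path}")
    n_channels = meta.get("n_channels")
    if n_channels is None:
        raise UnreadableFileError(f"binary file {path} needs an n_channels sidecar entry")
    raw = np.frombuffer(path.read_bytes(), dtype="<f8")
    if raw.size % n_channels != 0:
        raise InconsistentChannelsError(
            f"{raw.size} values do not divide into {n_channels} channels"
        )
    data = raw.reshape(n_channels, -1)
    if spec.orientation == "samples-by-channels":
        data = raw.reshape(-1, n_channels).T
    return Recording(data.copy(), float(srate), meta.get("channel_labels"))


def _read_text(path: Path, spec: RecordingFileSpec) -> Recording:
    if not spec.srate:
        raise MissingSrateError(f"no sampling rate for headerless file {path}")
    rows: List[List[float]] = []
    try:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(v) for v in line.replace(",", " ").split()])
    except ValueError as exc:
        raise UnreadableFileError(f"failed to parse {path}: {exc}") from exc
    if not rows:
        raise UnreadableFileError(f"{path} contains no data")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise InconsistentChannelsError(f"ragged rows in {path}: widths {sorted(widths)}")
    data = np.asarray(rows, dtype=np.float64)
    if spec.orientation == "samples-by-channels":
        data = data.T
    return Recording(data, float(spec.srate))


def write_recording(rec: Recording, path, fmt: str) -> Path:
    """Write a recording; the inverse of :func:`read_recording` per format."""
    path = Path(path)
    try:
        if fmt == "binary-float":
            path.write_bytes(np.ascontiguousarray(rec.data, dtype="<f8").tobytes())
            sidecar = {
                "n_channels": rec.n_channels,
                "n_samples": rec.n_samples,
                "srate": rec.srate,
                "channel_labels": rec.channel_labels,
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(sidecar, indent=1)
            )
        elif fmt == "delimited-text":
            np.savetxt(path, rec.data.T, fmt="%.10g", delimiter="\t")
        elif fmt == "edf":
            _write_edf(rec, path)
        else:
            raise WriteFailedError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise WriteFailedError(f"could not write {path}: {exc}") from exc
    return path


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: one data record holding the whole recording.

    Samples are scaled per channel to the signed 16-bit range, so precision
    is limited to ~1/65000 of the channel's amplitude span.
    """
    n_ch, n_samp = rec.data.shape
    labels = rec.channel_labels or [f"ch{i}" for i in range(n_ch)]
    duration = n_samp / rec.srate

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),          # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad("1", 8),                   # number of data records
            pad(f"{duration:.6g}", 8),     # record duration, seconds
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(lbl, 16) for lbl in labels],
        [pad("", 80)] * n_ch,              # transducer
        [pad("au", 8)] * n_ch,             # physical dimension
        [pad(f"{v:.8g}"[:8], 8) for v in phys_min],
        [pad(f"{v:.8g}"[:8], 8) for v in phys_max],
        [pad("-32768", 8)] * n_ch,
        [pad("32767", 8)] * n_ch,
        [pad("", 80)] * n_ch,              # prefiltering
        [pad(str(n_samp), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(f) for f in fields)

    # physical min/max are re-parsed from their 8-char ASCII form so the
    # digital->physical mapping matches exactly what a reader will compute
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / 65535.0
    digital = np.round((rec.data - pmin[:, None]) / gain[:, None]) - 32768
    digital = np.clip(digital, -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())  # channel-sequential within the record


def write_outputs(
    cleaned: Recording,
    report: CleaningReport,
    outdir,
    fmt: str = "binary-float",
    render_figures: Optional[bool] = None,
) -> dict:
    """Write the cleaned recording, the report JSON and optional figures.

    Returns a dict of the written paths.  Figures are rendered when
    ``render_figures`` is true, or by default when the configuration asks for
    plots.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"edf": ".edf", "binary-float": ".bin", "delimited-text": ".tsv"}[fmt]
    paths = {
        "cleaned": write_recording(cleaned, outdir / f"cleaned{ext}", fmt),
        "report": outdir / "report.json",
    }
    paths["report"].write_text(json.dumps(report.to_dict()))
    if render_figures is None:
        render_figures = report.final_config.plot_results
    if render_figures:
        from .report import render_frequency_figure

        figures = []
        for record in report.frequencies:
            figures.append(
                render_frequency_figure(
                    record,
                    report.raw_log_spectrum,
                    report.final_config,
                    outdir / f"noise_{record.frequency:.2f}Hz.png",
                )
            )
        paths["figures"] = figures
    return paths


def load_report_config(path) -> CleaningConfig:
    """Reload the exact configuration from a report JSON for replaying a run."""
    doc = json.loads(Path(path).read_text())
    return CleaningConfig.from_dict(doc["final_config"])
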