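"""The core spectral-split + spatial-filter cleaning operation on one chunk.

The chunk is split into a spectrally clean part and a noise-band residual
with a period-matched moving-average smoother whose frequency response has
nulls at the target frequency and all its harmonics; by construction
``smoothed + residual == chunk``.  The residual is decomposed by joint
decorrelation (DSS): a baseline covariance C0 and a covariance C1 biased
toward power at the noise frequency and its harmonics are jointly
diagonalized, ranking spatial components by how strongly they express the
noise.  The leading components are regressed out of the residual only, and
the smoothed part is added back — so the output keeps full rank and no
spectral notch is carved outside the noise band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.ndimage

from .core import CleaningConfig, Recording
from .errors import (
    ChunkShorterThanNfftError,
    DegenerateCovarianceError,
    FrequencyTooHighError,
    NRemoveOutOfRangeError,
)

__all__ = [
    "DssDecomposition",
    "smooth_split",
    "bias_covariances",
    "dss_decompose",
    "remove_components",
    "zapline_chunk",
    "decompose_chunk",
    "default_nfft",
]


@dataclass
class DssDecomposition:
    """Joint-decorrelation result: channels -> components rotation and scores."""

    rotation: np.ndarray     # channels x components
    scores: np.ndarray       # per-component noise-power ratios, descending
    n_effective: int         # retained dimensions after whitening truncation


def smooth_split(chunk: Recording, f: float) -> Tuple[Recording, Recording]:
    """Split a chunk into a smoothed part and its noise-band complement.

    The smoother is a moving average of length ``srate / f`` samples —
    fractional lengths are realized by linearly interpolating between the two
    flanking integer lengths — so it passes everything except ``f`` and its
    harmonics, which it nulls.  Edges use reflection padding; the identity
    ``smoothed + residual == chunk`` holds exactly because the residual is
    defined as the complement.
    """
    if f >= chunk.nyquist:
        raise FrequencyTooHighError(f"{f} Hz is at or above Nyquist ({chunk.nyquist})")
    period = chunk.srate / f
    n1 = int(np.floor(period))
    if n1 < 1:
        raise FrequencyTooHighError(f"period {period:.3f} samples is below 1")
    w = period - n1
    smoothed = scipy.ndimage.uniform_filter1d(
        chunk.data, size=n1, axis=-1, mode="reflect"
    )
    if w > 0:
        smoothed = (1.0 - w) * smoothed + w * scipy.ndimage.uniform_filter1d(
            chunk.data, size=n1 + 1, axis=-1, mode="reflect"
        )
    residual = chunk.data - smoothed
    return (
        Recording(smoothed, chunk.srate, chunk.channel_labels),
        Recording(residual, chunk.srate, chunk.channel_labels),
    )


def default_nfft(srate: float, n_samples: int) -> int:
    """FFT window for the biased covariance: 2^round(log2(srate)), capped."""
    nfft = int(2 ** round(np.log2(srate)))
    return min(nfft, n_samples)


def _harmonic_bins(f: float, srate: float, nfft: int) -> np.ndarray:
    """rFFT bin indices nearest k*f for k = 1 .. floor(Nyquist / f)."""
    k_max = int(np.floor((srate / 2.0) / f))
    bins = np.round(np.arange(1, k_max + 1) * f * nfft / srate).astype(int)
    return np.unique(bins[(bins >= 1) & (bins <= nfft // 2)])


def bias_covariances(
    residual: Recording, f: float, nfft: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Baseline and noise-biased channel covariances of the residual.

    C0 is the plain covariance.  C1 is the covariance of the residual
    reconstructed from only the DFT bins nearest the harmonics k*f, averaged
    over consecutive length-``nfft`` windows — the biasing matrix that makes
    the joint diagonalization rank components by noise power.
    """
    X = residual.data
    if X.shape[1] < nfft:
        raise ChunkShorterThanNfftError(
            f"chunk of {X.shape[1]} samples is shorter than nfft = {nfft}"
        )
    C0 = np.cov(X)
    bins = _harmonic_bins(f, residual.srate, nfft)
    n_win = X.shape[1] // nfft
    C1 = np.zeros_like(C0)
    for i in range(n_win):
        seg = X[:, i * nfft : (i + 1) * nfft]
        Y = np.fft.rfft(seg, axis=-1)
        mask = np.zeros(Y.shape[1], dtype=bool)
        mask[bins] = True
        recon = np.fft.irfft(np.where(mask, Y, 0.0), n=nfft, axis=-1)
        C1 += recon @ recon.T / nfft
    C1 /= n_win
    return C0, 0.5 * (C1 + C1.T)


def dss_decompose(C0: np.ndarray, C1: np.ndarray, nkeep: int = 0) -> DssDecomposition:
    """Jointly diagonalize baseline and biased covariances.

    C0 is whitened through its eigendecomposition (eigenvalues below
    1e-9 x the largest are discarded; at most ``nkeep`` dimensions are kept
    when ``nkeep`` > 0), then the whitened C1 is eigendecomposed.  Components
    come out sorted by descending noise-power score and are mutually
    uncorrelated with respect to C0.
    """
    C0 = np.asarray(C0, dtype=np.float64)
    C1 = np.asarray(C1, dtype=np.float64)
    if not np.any(C0):
        raise DegenerateCovarianceError("baseline covariance is all zero")
    d, V = np.linalg.eigh(0.5 * (C0 + C0.T))
    order = np.argsort(d)[::-1]
    d, V = d[order], V[:, order]
    keep = d > 1e-9 * d[0]
    if nkeep > 0:
        keep &= np.arange(d.size) < nkeep
    d, V = d[keep], V[:, keep]
    W = V / np.sqrt(d)  # whitening: W.T @ C0 @ W = I
    C1w = W.T @ C1 @ W
    e, E = np.linalg.eigh(0.5 * (C1w + C1w.T))
    order = np.argsort(e)[::-1]
    e, E = e[order], E[:, order]
    return DssDecomposition(
        rotation=W @ E,
        scores=np.maximum(e, 0.0),
        n_effective=int(d.size),
    )


def remove_components(
    residual: Recording, dss: DssDecomposition, n_remove: int
) -> Recording:
    """Regress the first ``n_remove`` component time courses out of every channel."""
    if not 0 <= n_remove <= dss.n_effective:
        raise NRemoveOutOfRangeError(
            f"n_remove = {n_remove} outside [0, {dss.n_effective}]"
        )
    if n_remove == 0:
        return Recording(residual.data.copy(), residual.srate, residual.channel_labels)
    T = (dss.rotation[:, :n_remove].T @ residual.data).T  # samples x n_remove
    coef, *_ = np.linalg.lstsq(T, residual.data.T, rcond=None)
    cleaned = residual.data - (T @ coef).T
    return Recording(cleaned, residual.srate, residual.channel_labels)


def decompose_chunk(
    chunk: Recording, f: float, cfg: CleaningConfig
) -> Tuple[Recording, Recording, DssDecomposition]:
    """smooth_split + biased covariances + DSS for one chunk at frequency ``f``."""
    smoothed, residual = smooth_split(chunk, f)
    nfft = default_nfft(chunk.srate, chunk.n_samples)
    C0, C1 = bias_covariances(residual, f, nfft)
    dss = dss_decompose(C0, C1, cfg.nkeep)
    return smoothed, residual, dss


def zapline_chunk(
    chunk: Recording, f: float, n_remove: int, cfg: CleaningConfig
) -> Tuple[Recording, np.ndarray]:
    """Clean one chunk at frequency ``f`` removing ``n_remove`` components.

    Returns the cleaned chunk (smoothed part plus denoised residual) and the
    DSS scores for the component selector and the report.  Removing zero
    components is the exact identity.
    """
    smoothed, residual, dss = decompose_chunk(chunk, f, cfg)
    if n_remove == 0:
        return chunk.copy(), dss.scores
    denoised = remove_components(residual, dss, n_remove)
    clean = Recording(
        smoothed.data + denoised.data, chunk.srate, chunk.channel_labels
    )
    return clean, dss.scores
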