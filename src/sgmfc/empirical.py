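"""Coherence-based band FC from multichannel region time series.

Mirrors the empirical pipeline used for source-level MEG: band-pass filter,
split into equal-duration epochs, multitaper cross-spectra, magnitude
coherence per frequency, band average. Cross-spectra are accumulated across
epochs and tapers before normalization, so the coherence estimate sharpens
as epochs accumulate (the behavior of the standard connectivity toolboxes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Union

import numpy as np
from scipy import signal

from .exceptions import DegenerateScaleError, DomainError, SegmentationError
from .forward import BandFC, BandSpec, SharedFC

__all__ = [
    "RegionalRecording",
    "epoch_split",
    "band_coherence",
    "minmax_vectorize",
    "vectorize_upper",
]


@dataclass(frozen=True)
class RegionalRecording:
    """``N x T`` real region-level time series sampled at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    epoch_count: int = 1

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 2:
            raise ValueError(f"data must be N x T, got shape {d.shape}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.epoch_count < 1:
            raise ValueError("epoch_count must be >= 1")
        if not np.all(np.isfinite(d)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


def epoch_split(rec: RegionalRecording, n_epochs: int) -> List[np.ndarray]:
    """Contiguous, equal-length, non-overlapping segments; remainder dropped."""
    if n_epochs < 1:
        raise SegmentationError("n_epochs must be >= 1")
    seg_len = rec.n_samples // n_epochs
    if seg_len < 1:
        raise SegmentationError(
            f"cannot split {rec.n_samples} samples into {n_epochs} epochs"
        )
    return [rec.data[:, k * seg_len:(k + 1) * seg_len] for k in range(n_epochs)]


def _dpss_tapers(n: int, nw: float) -> np.ndarray:
    k = max(1, int(2 * nw) - 1)
    tapers = signal.windows.dpss(n, NW=nw, Kmax=k)
    return np.atleast_2d(tapers)


def band_coherence(
    rec: RegionalRecording,
    band: BandSpec,
    n_epochs: int = 100,
    nw: float = 4.0,
    filter_band: bool = True,
) -> BandFC:
    """Magnitude coherence FC for one band.

    For regions i, j with tapered epoch spectra ``Y``, the per-frequency
    coherence is ``|S_ij| / sqrt(S_ii S_jj)`` with cross-spectra ``S``
    accumulated over epochs and tapers, and the band FC is its average over
    the in-band frequency bins. Symmetric, zero diagonal, entries in [0, 1].

    ``nw`` is the DPSS time-bandwidth product (2*nw - 1 tapers).
    """
    nyquist = rec.fs / 2.0
    if band.f_hi >= nyquist:
        raise DomainError(
            f"band upper edge {band.f_hi} Hz at or above Nyquist {nyquist} Hz"
        )
    data = rec.data
    if np.ptp(data) == 0:
        raise DegenerateScaleError("constant recording has no spectral content")
    if filter_band:
        sos = signal.butter(4, [band.f_lo, band.f_hi], btype="bandpass",
                            fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    segments = epoch_split(RegionalRecording(data, rec.fs), n_epochs)
    seg_len = segments[0].shape[1]
    min_len = int(2 * rec.fs / band.f_lo)  # two cycles of the slowest component
    if seg_len < min_len:
        warnings.warn(
            f"epoch length {seg_len} below the filter transient scale ({min_len} "
            f"samples); coherence estimates may be biased", stacklevel=2,
        )
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / rec.fs)
    in_band = np.flatnonzero((freqs >= band.f_lo) & (freqs <= band.f_hi))
    if in_band.size == 0:
        in_band = np.array([int(np.argmin(np.abs(freqs - band.mean_frequency)))])
    tapers = _dpss_tapers(seg_len, nw)
    n = rec.n_regions
    sxy = np.zeros((n, n, in_band.size), dtype=complex)
    for seg in segments:
        spectra = np.fft.rfft(tapers[:, np.newaxis, :] * seg[np.newaxis, :, :], axis=-1)
        spectra = spectra[:, :, in_band]  # (K, N, F)
        sxy += np.einsum("knf,kmf->nmf", spectra, spectra.conj())
    auto = np.real(np.einsum("nnf->nf", sxy))
    denom = np.sqrt(auto[:, np.newaxis, :] * auto[np.newaxis, :, :])
    if np.any(denom <= 0):
        raise DegenerateScaleError("zero auto-spectrum in band; cannot normalize")
    coh = np.abs(sxy) / denom
    m = coh.mean(axis=-1)
    m = 0.5 * (m + m.T)
    np.clip(m, 0.0, 1.0, out=m)
    np.fill_diagonal(m, 0.0)
    return BandFC(band=band, matrix=m, source="empirical")


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle (excluding the diagonal), row-major — the canonical
    FC vectorization used everywhere in the package."""
    m = np.asarray(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def minmax_vectorize(fc: Union[BandFC, np.ndarray]) -> np.ndarray:
    """Upper-triangle vector rescaled linearly to [0, 1].

    Invariant under positive affine transforms of the input; raises on
    constant input where the scale is degenerate.
    """
    matrix = fc.matrix if isinstance(fc, BandFC) else np.asarray(fc)
    v = vectorize_upper(matrix)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateScaleError("constant FC has no minmax scale")
    return (v - lo) / (hi - lo)


def minmax_vectorize_shared(shared: SharedFC) -> np.ndarray:
    """Concatenation of per-block minmax vectors, in block order."""
    return np.concatenate([minmax_vectorize(b) for b in shared.blocks])
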