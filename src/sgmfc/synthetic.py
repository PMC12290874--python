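"""Synthetic connectomes, FC observations and model-consistent time series.

Emulates the gross organization of an atlas-level structural connectome:
two hemispheric modules with denser/stronger intra- than inter-hemispheric
connections, interhemispheric homolog pairs, and Euclidean distances
between 3-D region centroids arranged in two clusters. Observations are
forward-model band FC plus entry-wise Gaussian noise; time series are
synthesized directly from the model's frequency-domain transfer function
driven by white noise, so their coherence approaches the model band FC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .empirical import RegionalRecording
from .forward import BandFC, BandSpec, DEFAULT_BANDS, SharedFC, band_fc, gamma_response
from .graph import StructuralConnectome, preprocess_sc
from .params import SGMParams

__all__ = [
    "SyntheticSpec",
    "generate_connectome",
    "SyntheticObservation",
    "generate_observation",
    "generate_timeseries",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic connectome.

    Densities are connection probabilities within/between hemispheres;
    scales are typical weights with a heavy-tailed log-normal spread
    (``weight_sigma``, in log units) — tractography weight matrices span
    orders of magnitude, which is what makes the extreme-value capping
    step of the preprocessing meaningful. Weights also decay exponentially
    with centroid distance (length scale ``distance_decay_mm``), as
    streamline counts do. ``geometry_scale_mm`` sets the hemispheric
    separation and cluster spread of the 3-D centroids, so distances land
    in a realistic 20–150 mm range.
    """

    n_regions: int = 16
    intra_density: float = 0.6
    inter_density: float = 0.25
    intra_scale: float = 1.0
    inter_scale: float = 0.4
    weight_sigma: float = 1.0
    distance_decay_mm: float = 45.0
    geometry_scale_mm: float = 70.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 4 or self.n_regions % 2:
            raise ValueError("n_regions must be even and >= 4 for hemispheric pairing")
        for d in (self.intra_density, self.inter_density):
            if not 0 < d <= 1:
                raise ValueError("densities must lie in (0, 1]")


#: preset mirroring the 68-region cortical atlas scale
ATLAS68 = SyntheticSpec(n_regions=68)


def generate_connectome(spec: SyntheticSpec = SyntheticSpec()) -> StructuralConnectome:
    """Random modular symmetric connectome with hemispheric block structure.

    Left regions are indices ``0..N/2-1``, right regions ``N/2..N-1``;
    region ``i`` and ``i + N/2`` form a homolog pair and are always
    connected. A within-hemisphere nearest-neighbour chain guarantees no
    region is isolated.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    nh = n // 2
    half = spec.geometry_scale_mm / 2.0
    spread = spec.geometry_scale_mm * 0.35
    centroids = np.empty((n, 3))
    centroids[:nh] = [-half, 0.0, 0.0] + rng.normal(0.0, spread, size=(nh, 3))
    centroids[nh:] = [+half, 0.0, 0.0] + rng.normal(0.0, spread, size=(nh, 3))
    diff = centroids[:, np.newaxis, :] - centroids[np.newaxis, :, :]
    distances = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(distances, 0.0)

    hemi = np.array(["L"] * nh + ["R"] * nh)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = hemi[i] == hemi[j]
            density = spec.intra_density if same else spec.inter_density
            scale = spec.intra_scale if same else spec.inter_scale
            if rng.random() < density:
                decay = np.exp(-distances[i, j] / spec.distance_decay_mm)
                w[i, j] = scale * decay * rng.lognormal(0.0, spec.weight_sigma)
    homologs = tuple((i, i + nh) for i in range(nh))
    for i, j in homologs:
        w[i, j] = max(w[i, j], spec.inter_scale)
    for h0 in (0, nh):  # chain within each hemisphere: no isolated regions
        for i in range(h0, h0 + nh - 1):
            w[i, i + 1] = max(w[i, i + 1], 0.1 * spec.intra_scale)
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    ids = tuple(f"{h}{k:02d}" for h, k in zip(hemi, list(range(nh)) * 2))
    return StructuralConnectome(
        weights=w, distances=distances, region_ids=ids, hemisphere=tuple(hemi),
        homolog_pairs=homologs,
    )


@dataclass(frozen=True)
class SyntheticObservation:
    """Noisy band FC observations with the generating parameters recorded."""

    band_fcs: tuple
    theta: SGMParams
    noise_sd: float
    seed: int

    @property
    def shared(self) -> SharedFC:
        return SharedFC(self.band_fcs)


def generate_observation(
    sc: StructuralConnectome,
    theta: SGMParams,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticObservation:
    """Model band FC plus symmetric entry-wise Gaussian noise.

    Noise of standard deviation ``noise_sd`` is drawn i.i.d. on the upper
    triangle and mirrored, so every off-diagonal entry carries exactly that
    noise level before clipping to [0, 1]; the diagonal stays zero.
    """
    rng = np.random.default_rng(seed)
    fcs = []
    for b in bands:
        m = band_fc(sc, theta, b).matrix.copy()
        if noise_sd > 0:
            n = m.shape[0]
            iu = np.triu_indices(n, k=1)
            noise = np.zeros_like(m)
            noise[iu] = rng.normal(0.0, noise_sd, size=iu[0].size)
            noise = noise + noise.T
            m = m + noise
        np.clip(m, 0.0, 1.0, out=m)
        np.fill_diagonal(m, 0.0)
        fcs.append(BandFC(band=b, matrix=m, source="empirical"))
    return SyntheticObservation(band_fcs=tuple(fcs), theta=theta,
                                noise_sd=noise_sd, seed=seed)


def generate_timeseries(
    sc: StructuralConnectome,
    theta: SGMParams,
    fs: float = 200.0,
    duration: float = 600.0,
    seed: int = 0,
    min_frequency: float = 2.0,
    chunk: int = 2048,
) -> RegionalRecording:
    """Real-valued region time series realizing the model's generative law.

    On the FFT grid, ``X(omega) = U(omega) Gamma(omega) U(omega)^H P(omega)``
    with i.i.d. circular complex white noise ``P``; Hermitian symmetry of
    the spectrum (real DC/Nyquist bins) makes the inverse transform real.
    The band coherence of a long recording approaches the model band FC.
    """
    if duration < 2.0 / min_frequency:
        raise ValueError(
            f"duration {duration} s too short to resolve {min_frequency} Hz"
        )
    if not sc.preprocessed:
        sc = preprocess_sc(sc)
    n_samp = int(round(fs * duration))
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    n = sc.n_regions
    rng = np.random.default_rng(seed)
    spectrum = np.empty((n, freqs.size), dtype=complex)
    delays = (sc.distances * 1e-3) / theta.v
    eye = np.eye(n, dtype=complex)
    for start in range(0, freqs.size, chunk):
        om = 2.0 * np.pi * freqs[start:start + chunk]
        laps = (eye[np.newaxis]
                - theta.alpha * sc.weights[np.newaxis]
                * np.exp(-1j * om[:, np.newaxis, np.newaxis] * delays[np.newaxis]))
        lam, u = np.linalg.eig(laps)
        fg = gamma_response(om, theta.tau_g)
        gam = 1.0 / (1j * om[:, np.newaxis] + lam * (fg / theta.tau_g)[:, np.newaxis])
        p = (rng.standard_normal((om.size, n)) + 1j * rng.standard_normal((om.size, n)))
        p /= np.sqrt(2.0)
        q = np.einsum("fmk,fm->fk", u.conj(), p)
        x = np.einsum("fnk,fk->fn", u, gam * q)
        spectrum[:, start:start + chunk] = x.T
    spectrum[:, 0] = spectrum[:, 0].real  # DC bin real
    if n_samp % 2 == 0:
        spectrum[:, -1] = spectrum[:, -1].real  # Nyquist bin real
    data = np.fft.irfft(spectrum, n=n_samp, axis=1)
    data /= data.std()  # overall amplitude is arbitrary; coherence is scale-free
    return RegionalRecording(data=data, fs=fs)
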