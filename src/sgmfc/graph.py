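"""Structural connectome container, preprocessing, and complex-Laplacian harmonics.

The structural graph is an ``N x N`` nonnegative symmetric weight matrix
(tract strengths in arbitrary units) together with an inter-region distance
matrix in millimetres. Finite conduction speed ``v`` turns each connection
into a delayed coupling ``c_ij * exp(-j*omega*d_ij/v)``; collecting these in
``C*(omega)`` gives the frequency-dependent complex Laplacian

    L(omega; alpha, v) = I - alpha * C*(omega; v),

whose eigenvectors ("harmonics") carry the spatial patterns on which the
model's functional connectivity is built.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    NumericalDegeneracyError,
)

__all__ = [
    "StructuralConnectome",
    "HarmonicBasis",
    "preprocess_sc",
    "complex_laplacian",
    "harmonics",
]

_SYM_TOL = 1e-8


def _check_symmetric(m: np.ndarray, name: str) -> None:
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > _SYM_TOL * scale:
        raise ValueError(f"{name} matrix is not symmetric within tolerance")


@dataclass(frozen=True)
class StructuralConnectome:
    """Weights, distances and region bookkeeping for one structural graph.

    ``weights``
        ``N x N`` nonnegative symmetric, zero diagonal (tract counts or,
        after :func:`preprocess_sc`, degree-normalized strengths).
    ``distances``
        ``N x N`` nonnegative symmetric, zero diagonal, millimetres.
    ``region_ids`` / ``hemisphere``
        labels and "L"/"R" flags per region.
    ``homolog_pairs``
        optional interhemispheric homolog index pairs ``(i, j)``.
    ``preprocessed``
        set by :func:`preprocess_sc`; a preprocessed connectome passed to
        :func:`preprocess_sc` again is returned unchanged.
    """

    weights: np.ndarray
    distances: np.ndarray
    region_ids: tuple
    hemisphere: tuple
    homolog_pairs: Optional[tuple] = None
    preprocessed: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        object.__setattr__(self, "hemisphere", tuple(self.hemisphere))
        if self.homolog_pairs is not None:
            object.__setattr__(
                self, "homolog_pairs", tuple((int(i), int(j)) for i, j in self.homolog_pairs)
            )
        n = w.shape[0]
        if w.ndim != 2 or w.shape != (n, n) or n < 2:
            raise ValueError(f"weights must be square with N >= 2, got shape {w.shape}")
        if d.shape != (n, n):
            raise ValueError("distances must have the same shape as weights")
        if len(self.region_ids) != n or len(self.hemisphere) != n:
            raise ValueError("region_ids / hemisphere length must equal N")
        if np.any(w < 0) or np.any(d < 0):
            raise ValueError("weights and distances must be nonnegative")
        if np.abs(np.diag(w)).max() > 0 or np.abs(np.diag(d)).max() > 0:
            raise ValueError("weights and distances must have zero diagonal")
        _check_symmetric(w, "weights")
        _check_symmetric(d, "distances")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def preprocess_sc(
    raw: StructuralConnectome,
    cap_percentile: float = 0.99,
    homolog_floor: Optional[float] = None,
) -> StructuralConnectome:
    """Cap extreme weights, floor homolog connections, degree-normalize.

    Steps, in order: (1) weights above the ``cap_percentile`` quantile of the
    nonzero entries are set to that quantile; (2) each homolog pair's weight
    is raised to at least ``homolog_floor`` (default: 1% of the cap value);
    (3) re-symmetrize; (4) symmetric sqrt-degree normalization
    ``w_ij / sqrt(deg_i * deg_j)`` so the coupling operator is well scaled
    (the zero-delay Laplacian then is the standard normalized graph
    Laplacian shifted by the coupling constant).

    Idempotent by contract: an already-preprocessed connectome is returned
    unchanged.
    """
    if raw.preprocessed:
        return raw
    if not 0 < cap_percentile <= 1:
        raise DomainError(f"cap_percentile must lie in (0, 1], got {cap_percentile}")
    w = raw.weights.copy()
    nz = w[w > 0]
    if nz.size == 0:
        raise DegenerateInputError("all-zero weight matrix cannot be preprocessed")
    cap = float(np.quantile(nz, cap_percentile))
    np.minimum(w, cap, out=w)
    if homolog_floor is None:
        homolog_floor = 0.01 * cap
    if homolog_floor < 0:
        raise DomainError("homolog_floor must be nonnegative")
    if homolog_floor > 0:
        if not raw.homolog_pairs:
            raise ConfigurationError(
                "homolog_floor > 0 requires homolog_pairs on the connectome"
            )
        for i, j in raw.homolog_pairs:
            w[i, j] = w[j, i] = max(w[i, j], homolog_floor)
    w = 0.5 * (w + w.T)
    deg = w.sum(axis=1)
    if np.any(deg <= 0):
        isolated = np.flatnonzero(deg <= 0).tolist()
        raise DegenerateInputError(f"isolated regions after preprocessing: {isolated}")
    w = w / np.sqrt(np.outer(deg, deg))
    np.fill_diagonal(w, 0.0)
    return replace(raw, weights=w, preprocessed=True)


def complex_laplacian(
    sc: StructuralConnectome, omega: float, alpha: float, v: float
) -> np.ndarray:
    """Complex Laplacian ``I - alpha * C exp(-j*omega*d/v)`` at angular frequency ``omega``.

    Distances are stored in mm and converted to metres, so delays are
    ``d_ij[m] / v[m/s]`` seconds and ``omega`` is in rad/s. The diagonal is
    exactly one. ``alpha = 0`` gives the identity; ``omega = 0`` gives the
    real symmetric ``I - alpha*C``.
    """
    if v <= 0:
        raise DomainError(f"conduction speed v must be positive, got {v}")
    if omega < 0:
        raise DomainError(f"omega must be nonnegative, got {omega}")
    delays = (sc.distances * 1e-3) / v  # seconds
    cstar = sc.weights * np.exp(-1j * omega * delays)
    lap = np.eye(sc.n_regions, dtype=complex) - alpha * cstar
    return lap


@dataclass(frozen=True)
class HarmonicBasis:
    """Eigendecomposition of a complex Laplacian at one angular frequency.

    Eigenpairs are sorted by ascending eigenvalue modulus (ties broken by
    phase, then index); eigenvector columns have unit Euclidean norm with a
    deterministic phase convention (largest-magnitude component real
    positive). For a complex-symmetric Laplacian the basis is generally not
    unitary; ``U^H U = I`` holds exactly only at zero delay.
    """

    omega: float
    laplacian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    def reconstruct(self) -> np.ndarray:
        """``U diag(lambda) U^-1`` — should reproduce the Laplacian."""
        u = self.eigenvectors
        return u @ np.diag(self.eigenvalues) @ np.linalg.inv(u)


def harmonics(
    laplacian: np.ndarray, omega: float = 0.0, check: bool = True, tol: float = 1e-8
) -> HarmonicBasis:
    """General (non-Hermitian) eigendecomposition of the complex Laplacian.

    Raises :class:`NumericalDegeneracyError` with condition-number
    diagnostics when the eigenbasis fails to reconstruct the input within
    ``tol`` (relative Frobenius norm), which signals near-defectiveness.
    """
    lap = np.asarray(laplacian)
    if not np.all(np.isfinite(lap.real)) or not np.all(np.isfinite(lap.imag)):
        raise ValueError("laplacian contains non-finite entries")
    lam, u = np.linalg.eig(lap)
    # deterministic order: ascending modulus, then phase, then original index
    mod = np.round(np.abs(lam), 12)
    ang = np.round(np.angle(lam), 12)
    order = np.lexsort((np.arange(lam.size), ang, mod))
    lam = lam[order]
    u = u[:, order]
    u = u / np.linalg.norm(u, axis=0, keepdims=True)
    # phase convention: largest-|.| component of each column real positive
    anchor = np.argmax(np.abs(u), axis=0)
    phases = u[anchor, np.arange(u.shape[1])]
    u = u * np.exp(-1j * np.angle(phases))[np.newaxis, :]
    basis = HarmonicBasis(omega=float(omega), laplacian=lap, eigenvalues=lam, eigenvectors=u)
    if check:
        scale = max(np.linalg.norm(lap), 1e-30)
        resid = np.linalg.norm(basis.reconstruct() - lap) / scale
        if resid > tol:
            cond = np.linalg.cond(u)
            raise NumericalDegeneracyError(
                f"eigenbasis reconstruction residual {resid:.3e} exceeds {tol:.1e} "
                f"(cond(U) = {cond:.3e}); Laplacian is numerically non-diagonalizable"
            )
    return basis
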