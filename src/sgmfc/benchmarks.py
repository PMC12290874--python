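"""Benchmark FC predictors: coupled Wilson–Cowan network and direct SC mapping.

The Wilson–Cowan benchmark couples one excitatory/inhibitory unit per
region through the structural graph,

    tau_e dE_i/dt = -E_i + (1 - E_i) S_e(c_ee E_i - c_ie I_i + O_i + P_i) + eps_e,
    tau_i dI_i/dt = -I_i + (1 - I_i) S_i(c_ei E_i - c_ii I_i + Q_i) + eps_i,

with network input ``O_i = K * sum_j c_ij E_j`` and sigmoid firing-rate
functions ``S(x) = 1/(1 + exp(-a (x - mu)))``. Integration is
Euler–Maruyama. Band FC is obtained from the simulated excitatory
trajectories with the same coherence machinery as for empirical data, and
the four global parameters (K, P0, Q0, noise intensity) are fitted with a
differential-evolution search against the Lin concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import optimize, signal

from .empirical import RegionalRecording, band_coherence, minmax_vectorize
from .exceptions import DegenerateScaleError, InstabilityError
from .forward import BandFC, BandSpec
from .graph import StructuralConnectome
from .metrics import lin_concordance

logger = logging.getLogger(__name__)

__all__ = [
    "WCParams",
    "WCTrajectory",
    "wilson_cowan_simulate",
    "nmm_band_fc",
    "EvolutionaryFitResult",
    "evolutionary_fit_nmm",
    "direct_mapping",
]


@dataclass(frozen=True)
class WCParams:
    """Wilson–Cowan constants. Local couplings and sigmoid shape default to
    the values of the standard open implementation of this model; the four
    globally fitted parameters are ``k_gl``, ``p0``, ``q0``, ``sigma``."""

    tau_e: float = 2.5        # ms
    tau_i: float = 3.75       # ms
    c_ee: float = 16.0
    c_ie: float = 12.0        # inhibitory -> excitatory
    c_ei: float = 15.0        # excitatory -> inhibitory
    c_ii: float = 3.0
    k_gl: float = 1.0         # global coupling
    p0: float = 0.5           # baseline excitatory drive
    q0: float = 0.5           # baseline inhibitory drive
    sigma: float = 0.01       # noise intensity
    gain: float = 1.5         # sigmoid slope a
    threshold: float = 3.0    # sigmoid threshold mu

    def __post_init__(self):
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("time constants must be positive")
        if self.sigma < 0:
            raise ValueError("noise intensity must be nonnegative")


@dataclass(frozen=True)
class WCTrajectory:
    """Excitatory/inhibitory trajectories (N x T) at time step ``dt`` ms."""

    E: np.ndarray
    I: np.ndarray
    dt: float
    seed: int

    def __post_init__(self):
        if self.E.shape != self.I.shape or self.E.ndim != 2:
            raise ValueError("E and I must be matching N x T arrays")
        if not (np.all(np.isfinite(self.E)) and np.all(np.isfinite(self.I))):
            raise ValueError("trajectory contains non-finite values")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz implied by the integration step."""
        return 1000.0 / self.dt


def _sigmoid(x: np.ndarray, gain: float, threshold: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-gain * (x - threshold)))


def wilson_cowan_simulate(
    sc: StructuralConnectome,
    params: WCParams,
    duration_ms: float = 61_000.0,
    dt: float = 0.1,
    seed: int = 0,
    burn_in_ms: float = 1000.0,
    init: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> WCTrajectory:
    """Euler–Maruyama integration of the coupled network.

    ``dt`` is in ms and must resolve the fastest time constant
    (``dt <= tau_e / 5``). The first ``burn_in_ms`` of the trajectory is
    discarded. Raises :class:`InstabilityError` (echoing the parameters) if
    activity leaves the sane range ``|E| <= 10``.
    """
    if dt <= 0 or dt > min(params.tau_e, params.tau_i) / 5.0:
        raise ValueError(
            f"dt = {dt} ms too coarse for tau_e = {params.tau_e} ms; "
            f"need dt <= tau/5 for stability"
        )
    n_steps = int(round(duration_ms / dt))
    n_burn = int(round(burn_in_ms / dt))
    if n_steps <= n_burn:
        raise ValueError("duration must exceed the burn-in")
    n = sc.n_regions
    rng = np.random.default_rng(seed)
    if init is None:
        e = np.full(n, 0.05)
        i = np.full(n, 0.05)
    else:
        e, i = np.array(init[0], dtype=float), np.array(init[1], dtype=float)
    coupling = params.k_gl * sc.weights
    sqrt_dt = np.sqrt(dt)
    out_e = np.empty((n, n_steps - n_burn))
    out_i = np.empty((n, n_steps - n_burn))
    for step in range(n_steps):
        net_input = coupling @ e
        drive_e = _sigmoid(params.c_ee * e - params.c_ie * i + net_input + params.p0,
                           params.gain, params.threshold)
        drive_i = _sigmoid(params.c_ei * e - params.c_ii * i + params.q0,
                           params.gain, params.threshold)
        de = (-e + (1.0 - e) * drive_e) / params.tau_e
        di = (-i + (1.0 - i) * drive_i) / params.tau_i
        if params.sigma > 0:
            e = e + dt * de + params.sigma * sqrt_dt * rng.standard_normal(n)
            i = i + dt * di + params.sigma * sqrt_dt * rng.standard_normal(n)
        else:
            e = e + dt * de
            i = i + dt * di
        if step % 1000 == 0 and np.abs(e).max() > 10.0:
            raise InstabilityError(
                f"Wilson–Cowan blow-up at t = {step * dt:.1f} ms "
                f"(|E|max = {np.abs(e).max():.2f}) with params {params}",
                params=params,
            )
        if step >= n_burn:
            out_e[:, step - n_burn] = e
            out_i[:, step - n_burn] = i
    if np.abs(out_e).max() > 10.0:
        raise InstabilityError("Wilson–Cowan trajectory left the sane range",
                               params=params)
    return WCTrajectory(E=out_e, I=out_i, dt=dt, seed=seed)


def nmm_band_fc(
    traj: WCTrajectory,
    band: BandSpec,
    n_epochs: int = 20,
    downsample_fs: float = 200.0,
) -> BandFC:
    """Band coherence of the simulated excitatory activity.

    The trajectory is resampled from the integration rate to
    ``downsample_fs`` before the coherence computation (all bands of
    interest are far below the integration Nyquist).
    """
    e = traj.E
    temporal_ptp = np.ptp(e, axis=1).max()
    if temporal_ptp < 1e-6 * max(np.abs(e).max(), 1e-30):
        raise DegenerateScaleError(
            "trajectory is constant in time (fixed point reached); "
            "no band structure")
    fs0 = traj.fs
    if downsample_fs < fs0:
        factor = fs0 / downsample_fs
        up, down = 1, int(round(factor))
        data = signal.resample_poly(e, up, down, axis=1)
        fs = fs0 / down
    else:
        data, fs = e, fs0
    rec = RegionalRecording(data=data, fs=fs, epoch_count=n_epochs)
    fc = band_coherence(rec, band, n_epochs=n_epochs)
    return BandFC(band=band, matrix=fc.matrix, source="benchmark")


@dataclass(frozen=True)
class EvolutionaryFitResult:
    """Best Wilson–Cowan global parameters and the per-generation loss trace."""

    params: WCParams
    best_loss: float
    loss_trace: tuple


_UNSTABLE_PENALTY = 10.0

#: search box for (K, P0, Q0, sigma)
_WC_FIT_BOUNDS = ((0.05, 5.0), (0.0, 2.0), (0.0, 2.0), (0.001, 0.2))


def evolutionary_fit_nmm(
    fc_obs: Union[BandFC, np.ndarray],
    sc: StructuralConnectome,
    generations: int = 10,
    pop_size: int = 16,
    seed: int = 0,
    band: Optional[BandSpec] = None,
    duration_ms: float = 61_000.0,
    dt: float = 0.2,
    base_params: Optional[WCParams] = None,
    n_epochs: int = 20,
) -> EvolutionaryFitResult:
    """Differential-evolution fit of (K, P0, Q0, sigma) to an observed FC.

    The loss is ``1 - Lin`` between minmax-vectorized simulated and observed
    FC; unstable parameter sets receive a fixed penalty. The simulation seed
    is held fixed across evaluations so the objective is deterministic for
    the optimizer. Elitism of the evolutionary search makes the best loss
    non-increasing across generations.
    """
    if generations < 1:
        raise ValueError("need at least one generation")
    if band is None:
        band = fc_obs.band if isinstance(fc_obs, BandFC) else None
    if band is None:
        raise ValueError("band must be given when fc_obs carries none")
    base = base_params or WCParams()
    obs_vec = minmax_vectorize(fc_obs if isinstance(fc_obs, BandFC)
                               else np.asarray(fc_obs))

    def loss(x):
        p = replace(base, k_gl=float(x[0]), p0=float(x[1]), q0=float(x[2]),
                    sigma=float(x[3]))
        try:
            traj = wilson_cowan_simulate(sc, p, duration_ms=duration_ms, dt=dt,
                                         seed=seed)
            pred = nmm_band_fc(traj, band, n_epochs=n_epochs)
            return 1.0 - lin_concordance(minmax_vectorize(pred), obs_vec)
        except (InstabilityError, DegenerateScaleError):
            return _UNSTABLE_PENALTY

    trace: List[float] = []

    def callback(xk, convergence=None):
        trace.append(loss(xk))

    result = optimize.differential_evolution(
        loss, bounds=_WC_FIT_BOUNDS, maxiter=generations, popsize=pop_size,
        rng=np.random.default_rng(seed), polish=False, tol=0.0,
        callback=callback, init="sobol",
    )
    best_loss = float(result.fun)
    if best_loss >= _UNSTABLE_PENALTY:
        raise InstabilityError(
            "every evaluated Wilson–Cowan parameter set was unstable",
            params=base,
        )
    fitted = replace(base, k_gl=float(result.x[0]), p0=float(result.x[1]),
                     q0=float(result.x[2]), sigma=float(result.x[3]))
    return EvolutionaryFitResult(params=fitted, best_loss=best_loss,
                                 loss_trace=tuple(trace))


def direct_mapping(sc: StructuralConnectome,
                   band: Optional[BandSpec] = None) -> BandFC:
    """The preprocessed SC itself as a band-independent FC prediction."""
    if not sc.preprocessed:
        raise ValueError("direct mapping requires a preprocessed connectome")
    m = sc.weights.copy()
    np.fill_diagonal(m, 0.0)
    return BandFC(band=band, matrix=m, source="benchmark")
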