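"""Bayesian inference of the three global model parameters from band FC.

The pipeline follows the sequential simulation-based scheme:

1. *Parameter transformation.* Each bounded parameter is mapped to the real
   line with a rescaled logit, so the conditional density estimator works
   on an unconstrained space; the posterior over the original parameters is
   recovered with the Jacobian correction ``q(s) * |det J|``.
2. *Annealing-informed prior.* A dual-annealing global fit (default 200
   iterations, loss = 1 - Lin concordance on minmax-vectorized FC) yields a
   rough point estimate; the prior is a unit-covariance Gaussian centred on
   it in transformed space.
3. *Sequential posterior estimation.* Each of (by default) three rounds
   simulates M parameter/FC pairs from the current proposal, fits a
   conditional density of the transformed parameters given the
   (minmax-vectorized) FC, and conditions on the observation to form the
   next round's proposal.

The conditional density family is Gaussian: an MLP (two hidden layers of 50
units) learns the conditional mean from FC features, and the residual
covariance closes the density. Fitting the MLP by least squares maximizes
the Gaussian log-likelihood for a fixed covariance, so each round performs
the same maximum-likelihood objective as flow-based neural posterior
estimation within this family. The conditioned density is used directly as
the next round's proposal (no analytic proposal correction: with a
regression-based q whose covariance reflects estimator error rather than
the exact proposal-posterior, the Gaussian importance correction divides
two nearly equal precisions and amplifies regression noise by their
ratio).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats
from sklearn.decomposition import PCA
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .empirical import minmax_vectorize, minmax_vectorize_shared
from .exceptions import DomainError
from .forward import BandFC, BandSpec, SharedFC, band_fc
from .graph import StructuralConnectome
from .params import LOWER, PARAM_NAMES, SGMParams, UPPER

logger = logging.getLogger(__name__)

__all__ = [
    "to_unbounded",
    "from_unbounded",
    "log_abs_det_jacobian",
    "GaussianPrior",
    "annealing_prior",
    "SimulationBatch",
    "simulate_pairs",
    "PosteriorEstimate",
    "train_posterior",
    "fit_shared",
]


# ---------------------------------------------------------------------------
# logit reparameterization


def to_unbounded(theta: Union[SGMParams, np.ndarray]) -> np.ndarray:
    """Per-coordinate logit of ``(theta - lo)/(hi - lo)``; bounds map to +-inf.

    ``theta`` must lie strictly inside the admissible box; a coordinate on
    or outside a bound raises a :class:`DomainError` naming it.
    """
    arr = theta.as_array() if isinstance(theta, SGMParams) else np.asarray(theta, float)
    for k, name in enumerate(PARAM_NAMES):
        if not LOWER[k] < arr[k] < UPPER[k]:
            raise DomainError(
                f"{name} = {arr[k]} not strictly inside ({LOWER[k]}, {UPPER[k]})"
            )
    frac = (arr - LOWER) / (UPPER - LOWER)
    return np.log(frac) - np.log1p(-frac)


def from_unbounded(s: np.ndarray) -> SGMParams:
    """Inverse transform: sigmoid rescaled to the admissible box."""
    s = np.asarray(s, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-s))
    arr = LOWER + (UPPER - LOWER) * sig
    # guard against floating-point saturation exactly onto a bound
    eps = 1e-12 * (UPPER - LOWER)
    arr = np.clip(arr, LOWER + eps, UPPER - eps)
    return SGMParams.from_array(arr)


def log_abs_det_jacobian(s: np.ndarray) -> float:
    """``log |det J|`` of the forward (theta -> s) transform, evaluated at
    ``theta(s)``. The transform is coordinate-wise, so the log-determinant
    is a sum of per-coordinate derivative logs:
    ``d s_k / d theta_k = (hi-lo) / ((theta-lo)(hi-theta))``.
    """
    s = np.asarray(s, dtype=float)
    # (theta-lo)(hi-theta) = (hi-lo)^2 sigma(s)(1-sigma(s));
    # log sigma(s) = -softplus(-s), log(1-sigma(s)) = -softplus(s)
    softplus = np.logaddexp(0.0, s) + np.logaddexp(0.0, -s)
    return float(np.sum(softplus - np.log(UPPER - LOWER)))


# ---------------------------------------------------------------------------
# observation featurization


def _features(obs: Union[BandFC, SharedFC, np.ndarray]) -> np.ndarray:
    if isinstance(obs, SharedFC):
        return minmax_vectorize_shared(obs)
    return minmax_vectorize(obs)


def _matrix_features(matrices: Sequence[np.ndarray]) -> np.ndarray:
    return np.concatenate([minmax_vectorize(m) for m in matrices])


# ---------------------------------------------------------------------------
# Gaussian distributions over the transformed parameters


@dataclass(frozen=True)
class GaussianPrior:
    """Multivariate Gaussian over the transformed parameter vector ``s``."""

    mean: np.ndarray
    cov: np.ndarray
    theta_hat: Optional[SGMParams] = None
    #: optional defensive mixture component: (weight, mean, cov) of a wide
    #: fallback Gaussian mixed into the samples to avoid proposal collapse
    defensive: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        if self.mean.shape != (3,) or self.cov.shape != (3, 3):
            raise ValueError("prior must be over the 3-vector s")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        draws = rng.multivariate_normal(self.mean, self.cov, size=n)
        if self.defensive is not None:
            w, d_mean, d_cov = self.defensive
            mask = rng.random(n) < w
            if mask.any():
                draws[mask] = rng.multivariate_normal(
                    np.asarray(d_mean, float), np.asarray(d_cov, float),
                    size=int(mask.sum()))
        return draws

    def logpdf(self, s: np.ndarray) -> np.ndarray:
        return stats.multivariate_normal(self.mean, self.cov, allow_singular=False
                                         ).logpdf(s)


def _bands_of(obs: Union[BandFC, SharedFC],
              bands: Optional[Sequence[BandSpec]]) -> Tuple[BandSpec, ...]:
    if bands is not None:
        return tuple(bands)
    if isinstance(obs, SharedFC):
        return tuple(b.band for b in obs.blocks)
    if obs.band is None:
        raise ValueError("observation has no band; pass bands explicitly")
    return (obs.band,)


def _forward_matrices(sc: StructuralConnectome, params: SGMParams,
                      bands: Sequence[BandSpec]) -> List[np.ndarray]:
    return [band_fc(sc, params, b).matrix for b in bands]


def annealing_prior(
    fc_obs: Union[BandFC, SharedFC],
    sc: StructuralConnectome,
    bands: Optional[Sequence[BandSpec]] = None,
    n_iter: int = 200,
    seed: int = 0,
) -> GaussianPrior:
    """Dual-annealing point fit, returned as an N(s_hat, I) prior.

    Minimizes ``1 - Lin(minmax model FC, minmax observed FC)`` over the
    admissible parameter box (default 200 global iterations). On optimizer
    failure, falls back with a warning to a standard-normal prior centred at
    ``s = 0`` (the box midpoints).
    """
    from .metrics import lin_concordance  # local import avoids cycle at module load

    bands = _bands_of(fc_obs, bands)
    obs_vec = _features(fc_obs)
    margin = 1e-9 * (UPPER - LOWER)
    box = list(zip(LOWER + margin, UPPER - margin))

    def objective(theta_arr):
        try:
            model_vec = _matrix_features(
                _forward_matrices(sc, SGMParams.from_array(theta_arr), bands))
            return 1.0 - lin_concordance(model_vec, obs_vec)
        except Exception:  # degenerate draw: worst possible loss
            return 2.0

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = optimize.dual_annealing(
                objective, bounds=box, maxiter=n_iter,
                rng=np.random.default_rng(seed),
                minimizer_kwargs={"method": "L-BFGS-B",
                                  "options": {"maxiter": 25}},
            )
        if not np.all(np.isfinite(result.x)):
            raise RuntimeError("non-finite annealing solution")
    except Exception as exc:  # pragma: no cover - defensive fallback
        warnings.warn(f"dual annealing failed ({exc}); falling back to the "
                      f"mid-box prior", stacklevel=2)
        return GaussianPrior(mean=np.zeros(3), cov=np.eye(3))
    theta_hat = SGMParams.from_array(np.clip(result.x, LOWER + margin, UPPER - margin))
    s_hat = to_unbounded(theta_hat)
    logger.info("annealing estimate theta=%s loss=%.4f", theta_hat, result.fun)
    return GaussianPrior(mean=s_hat, cov=np.eye(3), theta_hat=theta_hat)


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class SimulationBatch:
    """Simulated parameter/FC pairs: ``s`` (M x 3) and per-draw noisy band
    matrices. ``n_resampled`` counts forward-model failures that were
    redrawn."""

    s: np.ndarray
    matrices: tuple  # tuple of lists of N x N arrays, one list per draw
    n_resampled: int = 0

    def __len__(self) -> int:
        return self.s.shape[0]


def simulate_pairs(
    prior: GaussianPrior,
    sc: StructuralConnectome,
    bands: Sequence[BandSpec],
    M: int = 1000,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SimulationBatch:
    """Draw ``s ~ prior``, run the forward model per band, add i.i.d.
    Gaussian entry noise of standard deviation ``noise_sd``.

    A draw whose forward evaluation fails is resampled (counted and
    reported via the returned batch). The observation itself is never
    noise-augmented; noise enters only these training simulations.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    n = sc.n_regions
    iu = np.triu_indices(n, k=1)
    s_rows, mats, n_resampled = [], [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while len(s_rows) < M:
            s = prior.sample(1, rng)[0]
            try:
                clean = _forward_matrices(sc, from_unbounded(s), bands)
            except Exception:
                n_resampled += 1
                if n_resampled > 100 * M:
                    raise RuntimeError("forward model failing persistently")
                continue
            noisy = []
            for m in clean:
                if noise_sd > 0:
                    # same noise model as the synthetic observations:
                    # mirrored upper-triangle noise, clipped to the valid FC
                    # range, zero diagonal — the training simulator must
                    # match the observation model for valid conditioning
                    e = np.zeros_like(m)
                    e[iu] = rng.normal(0.0, noise_sd, size=iu[0].size)
                    m = np.clip(m + e + e.T, 0.0, 1.0)
                    np.fill_diagonal(m, 0.0)
                noisy.append(m)
            s_rows.append(s)
            mats.append(noisy)
    if n_resampled:
        logger.warning("simulate_pairs: %d forward-model failures resampled",
                       n_resampled)
    return SimulationBatch(s=np.array(s_rows), matrices=tuple(mats),
                           n_resampled=n_resampled)


# ---------------------------------------------------------------------------
# posterior estimation


@dataclass(frozen=True)
class PosteriorEstimate:
    """Gaussian posterior over transformed parameters, conditioned on one
    observation, with samples mapped back to the bounded space.

    ``log_density_theta`` evaluates the posterior density over the original
    parameters, ``q(s(theta)) * |det J|``; because the transform is a
    diffeomorphism onto the admissible box, the corrected density is a
    proper density on the box and every sample respects the bounds by
    construction.
    """

    mean_s: np.ndarray
    cov_s: np.ndarray
    observation: str
    prior: GaussianPrior
    theta_samples: np.ndarray
    rounds: int
    n_simulations: int

    @property
    def mean_theta(self) -> SGMParams:
        """Posterior mean in the original parameter space (sample average)."""
        return SGMParams.from_array(self.theta_samples.mean(axis=0))

    def sample_theta(self, n: int, rng: Optional[np.random.Generator] = None
                     ) -> np.ndarray:
        rng = rng or np.random.default_rng()
        s = rng.multivariate_normal(self.mean_s, self.cov_s, size=n)
        s = s[np.all(np.isfinite(s), axis=1)]  # reject non-finite draws
        return np.array([from_unbounded(row).as_array() for row in s])

    def log_density_s(self, s: np.ndarray) -> float:
        return float(stats.multivariate_normal(self.mean_s, self.cov_s).logpdf(s))

    def log_density_theta(self, theta: Union[SGMParams, np.ndarray]) -> float:
        s = to_unbounded(theta)
        return self.log_density_s(s) + log_abs_det_jacobian(s)

    def marginal_density_theta(self, k: int, theta_k: np.ndarray) -> np.ndarray:
        """Marginal posterior density of parameter ``k`` on a grid of values
        (1-D Gaussian marginal of ``s_k`` with its 1-D Jacobian factor)."""
        theta_k = np.asarray(theta_k, dtype=float)
        frac = (theta_k - LOWER[k]) / (UPPER[k] - LOWER[k])
        s_k = np.log(frac) - np.log1p(-frac)
        dens_s = stats.norm(self.mean_s[k], np.sqrt(self.cov_s[k, k])).pdf(s_k)
        jac = (UPPER[k] - LOWER[k]) / ((theta_k - LOWER[k]) * (UPPER[k] - theta_k))
        return dens_s * jac

    def summary(self) -> dict:
        out = {}
        for k, name in enumerate(PARAM_NAMES):
            col = self.theta_samples[:, k]
            out[name] = {
                "mean": float(col.mean()),
                "median": float(np.median(col)),
                "q05": float(np.quantile(col, 0.05)),
                "q95": float(np.quantile(col, 0.95)),
            }
        return out


def _fit_conditional_gaussian(
    x: np.ndarray, y: np.ndarray, x_obs: np.ndarray, seed: int,
    hidden: int = 50, embed_dim: int = 30,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit the conditional-Gaussian density of ``y`` given ``x`` and condition
    on ``x_obs``: returns (conditional mean at x_obs, residual covariance).

    The FC feature vector is embedded by PCA (noise averaging across the
    many correlated FC entries) before the MLP learns the conditional mean;
    minimizing squared error maximizes the Gaussian log-likelihood at fixed
    covariance, and the residual covariance closes the density.
    """
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    xo = scaler.transform(x_obs[np.newaxis, :])
    n_comp = min(embed_dim, xs.shape[0] - 1, xs.shape[1])
    embed = PCA(n_components=n_comp, random_state=0).fit(xs)
    xs = embed.transform(xs)
    xo = embed.transform(xo)

    def make_net():
        return MLPRegressor(
            hidden_layer_sizes=(hidden, hidden), activation="tanh",
            solver="lbfgs", alpha=1e-2, max_iter=400, random_state=seed,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = make_net().fit(xs, y)
        resid_in = y - net.predict(xs)
        obs_preds = [net.predict(xo)[0]]
        # Held-out folds serve two purposes: their residuals give an honest
        # (non-overfit) posterior covariance, and bagging their predictions
        # at the observation substantially reduces the variance of the
        # conditional mean, which is the accuracy bottleneck at small M.
        folds = np.arange(xs.shape[0]) % 5
        resid_cv = np.empty_like(y)
        for f in range(5):
            hold = folds == f
            fold_net = make_net().fit(xs[~hold], y[~hold])
            resid_cv[hold] = y[hold] - fold_net.predict(xs[hold])
            obs_preds.append(fold_net.predict(xo)[0])
    if not (np.all(np.isfinite(resid_in)) and np.all(np.isfinite(resid_cv))):
        raise RuntimeError("conditional-density training diverged "
                           "(non-finite residuals)")
    ridge = 1e-6 * np.eye(y.shape[1])
    cov_in = np.cov(resid_in.T) + ridge
    cov_cv = np.cov(resid_cv.T) + ridge
    # coordinate-wise median across the full-data and fold networks:
    # robust to an occasional wild fold prediction at the observation
    m_obs = np.median(obs_preds, axis=0)
    if not np.all(np.isfinite(m_obs)):
        raise RuntimeError("conditional mean at the observation is non-finite")
    return m_obs, cov_in, cov_cv


def train_posterior(
    fc_obs: Union[BandFC, SharedFC],
    sc: StructuralConnectome,
    bands: Optional[Sequence[BandSpec]] = None,
    rounds: int = 3,
    M: int = 1000,
    noise_sd: float = 1.0,
    seed: int = 0,
    prior: Optional[GaussianPrior] = None,
    annealing_iters: int = 200,
    n_posterior_samples: int = 1000,
    defensive_weight: float = 0.1,
) -> PosteriorEstimate:
    """Sequential posterior estimation (default 3 rounds x M=1000 simulations).

    Each round simulates parameter/FC pairs from the current proposal, fits
    the conditional density of transformed parameters given minmax-scaled
    FC vectors, and conditions on ``fc_obs`` to form the next proposal. The
    prior defaults to the annealing-informed Gaussian.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    bands = _bands_of(fc_obs, bands)
    x_obs = _features(fc_obs)
    if prior is None:
        prior = annealing_prior(fc_obs, sc, bands, n_iter=annealing_iters, seed=seed)
    proposal = prior
    seed_seq = np.random.SeedSequence(seed)
    round_seeds = seed_seq.generate_state(2 * rounds + 1) % (2 ** 31)
    mean_s, cov_s = proposal.mean, proposal.cov
    total_sims = 0
    for r in range(rounds):
        batch = simulate_pairs(proposal, sc, bands, M=M, noise_sd=noise_sd,
                               seed=int(round_seeds[2 * r]))
        total_sims += len(batch)
        x = np.array([_matrix_features(mats) for mats in batch.matrices])
        mean_q, cov_in, cov_cv = _fit_conditional_gaussian(
            x, batch.s, x_obs, seed=int(round_seeds[2 * r + 1]))
        # The proposal schedule zooms with the (tight) in-sample covariance,
        # which concentrates later-round simulations near the conditional
        # mean; the reported posterior uses the honest cross-validated
        # covariance instead. ``defensive_weight`` keeps a small fraction of
        # later-round simulations on the original prior as a guard against
        # zooming onto the wrong region; kept small because mixing many wide
        # draws into the training set dilutes the local regression.
        mean_s, cov_s = mean_q, cov_cv
        defensive = ((defensive_weight, prior.mean, prior.cov)
                     if defensive_weight > 0 else None)
        proposal = GaussianPrior(mean=mean_q, cov=cov_in, defensive=defensive)
        logger.info("round %d: posterior mean theta=%s", r + 1,
                    from_unbounded(mean_s))
    obs_tag = ("shared" if isinstance(fc_obs, SharedFC)
               else (fc_obs.band.name if fc_obs.band else "band"))
    sample_rng = np.random.default_rng(int(round_seeds[-1]))
    s_draws = sample_rng.multivariate_normal(mean_s, cov_s, size=n_posterior_samples)
    theta_samples = np.array([from_unbounded(row).as_array() for row in s_draws])
    return PosteriorEstimate(
        mean_s=mean_s, cov_s=cov_s, observation=obs_tag, prior=prior,
        theta_samples=theta_samples, rounds=rounds, n_simulations=total_sims,
    )


def fit_shared(
    fc_blocks: SharedFC,
    sc: StructuralConnectome,
    **kwargs,
) -> PosteriorEstimate:
    """Band-shared fit: identical pipeline conditioned on the stacked
    observation, inferring one parameter set for all bands jointly."""
    if not isinstance(fc_blocks, SharedFC):
        raise TypeError("fit_shared expects a SharedFC observation")
    return train_posterior(fc_blocks, sc, **kwargs)
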