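"""Similarity metrics, permutation/spin null standardization, regional evaluation.

Model predictions are scored against empirical FC with Pearson correlation,
Lin's concordance correlation coefficient, and mean squared error, computed
on minmax-scaled upper-triangle vectors. Because the raw scales of Lin and
MSE are hard to interpret, both are also reported standardized against a
null ensemble obtained by randomly permuting region identity (or by a spin
null that rotates regions on a sphere, preserving spatial autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, UndefinedMetricError
from .forward import BandFC

__all__ = [
    "lin_concordance",
    "pearson",
    "mse",
    "MetricsReport",
    "compute_metrics",
    "standardize_by_null",
    "regional_evaluation",
    "bonferroni_cutoff",
]


def _as_matrix(fc) -> np.ndarray:
    return fc.matrix if isinstance(fc, BandFC) else np.asarray(fc, dtype=float)


def _minmax_vec(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    v = m[iu]
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise UndefinedMetricError("constant FC vector; metrics undefined")
    return (v - lo) / (hi - lo)


def lin_concordance(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``2*cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
    population (1/n) moments. Equals Pearson's r exactly when means and
    variances of the two inputs match; penalized otherwise. Range [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise UndefinedMetricError("zero denominator in Lin concordance")
    return float(2.0 * np.mean((x - mx) * (y - my)) / denom)


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedMetricError("zero variance input to Pearson correlation")
    return float(np.corrcoef(x, y)[0, 1])


def mse(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((x - y) ** 2))


def _metric_on_fc(metric: Callable, emp: np.ndarray, pred: np.ndarray) -> float:
    return metric(_minmax_vec(emp), _minmax_vec(pred))


@dataclass(frozen=True)
class MetricsReport:
    """Raw and null-standardized similarity metrics for one (emp, pred) pair."""

    pearson: float
    lin: float
    mse: float
    standardized_pearson: float
    standardized_lin: float
    standardized_mse: float
    null: str
    n_null: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson, "lin": self.lin, "mse": self.mse,
            "standardized_pearson": self.standardized_pearson,
            "standardized_lin": self.standardized_lin,
            "standardized_mse": self.standardized_mse,
            "null": self.null, "n_null": self.n_null, "seed": self.seed,
        }


def _null_permutations(
    n: int, null: str, n_null: int, rng: np.random.Generator,
    coords: Optional[np.ndarray],
) -> List[np.ndarray]:
    if null == "shuffle":
        return [rng.permutation(n) for _ in range(n_null)]
    if null == "spin":
        if coords is None:
            raise ConfigurationError("spin null requires per-region coordinates")
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise ConfigurationError(f"coords must be N x 3, got {coords.shape}")
        unit = coords / np.linalg.norm(coords, axis=1, keepdims=True)
        perms = []
        for _ in range(n_null):
            rot = stats.special_ortho_group.rvs(3, random_state=rng)
            rotated = unit @ rot.T
            # optimal one-to-one reassignment region -> nearest rotated region
            _, perm = linear_sum_assignment(cdist(unit, rotated))
            perms.append(perm)
        return perms
    raise ConfigurationError(f"unknown null model {null!r}")


def standardize_by_null(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    fc_emp: Union[BandFC, np.ndarray],
    fc_pred: Union[BandFC, np.ndarray],
    null: str = "shuffle",
    n: int = 1000,
    seed: int = 0,
    coords: Optional[np.ndarray] = None,
) -> float:
    """Z-score ``metric_fn(emp, pred)`` against a null of permuted empirical FCs.

    ``metric_fn`` takes two matrices. The null permutes region identity of
    the empirical FC (joint row/column permutation for the shuffle null; a
    random sphere rotation with nearest-region reassignment for the spin
    null) and recomputes the metric ``n`` times; the raw value is returned
    standardized by the null mean and standard deviation.
    """
    emp = _as_matrix(fc_emp)
    pred = _as_matrix(fc_pred)
    raw = metric_fn(emp, pred)
    rng = np.random.default_rng(seed)
    perms = _null_permutations(emp.shape[0], null, n, rng, coords)
    null_vals = np.array([metric_fn(emp[p][:, p], pred) for p in perms])
    sd = null_vals.std()
    if sd == 0:
        # a metric invariant under the null permutations is, by definition,
        # exactly at its null expectation
        if np.abs(raw - null_vals.mean()) < 1e-10 * max(abs(raw), 1.0):
            return 0.0
        raise UndefinedMetricError("null distribution has zero spread")
    return float((raw - null_vals.mean()) / sd)


def compute_metrics(
    fc_emp: Union[BandFC, np.ndarray],
    fc_pred: Union[BandFC, np.ndarray],
    null: str = "shuffle",
    n_null: int = 1000,
    seed: int = 0,
    coords: Optional[np.ndarray] = None,
) -> MetricsReport:
    """Pearson/Lin/MSE on minmax vectors, raw and null-standardized."""
    emp = _as_matrix(fc_emp)
    pred = _as_matrix(fc_pred)
    fns = {
        "pearson": lambda a, b: _metric_on_fc(pearson, a, b),
        "lin": lambda a, b: _metric_on_fc(lin_concordance, a, b),
        "mse": lambda a, b: _metric_on_fc(mse, a, b),
    }
    raw = {k: f(emp, pred) for k, f in fns.items()}
    z = {
        k: standardize_by_null(f, emp, pred, null=null, n=n_null, seed=seed,
                               coords=coords)
        for k, f in fns.items()
    }
    return MetricsReport(
        pearson=raw["pearson"], lin=raw["lin"], mse=raw["mse"],
        standardized_pearson=z["pearson"], standardized_lin=z["lin"],
        standardized_mse=z["mse"], null=null, n_null=n_null, seed=seed,
    )


def bonferroni_cutoff(n_regions: int, alpha: float = 0.05) -> float:
    """Significance cutoff ``-ln(alpha / N)`` on the negative-log-p scale."""
    return float(-np.log(alpha / n_regions))


def _column_pearson(emp: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Per-region Pearson between matching FC columns, excluding the
    self-connection entry."""
    n = emp.shape[0]
    out = np.empty(n)
    for j in range(n):
        keep = np.arange(n) != j
        out[j] = pearson(emp[keep, j], pred[keep, j])
    return out


def regional_evaluation(
    pairs: Sequence[Tuple[Union[BandFC, np.ndarray], Union[BandFC, np.ndarray]]],
    null: str = "shuffle",
    n_null: int = 100,
    seed: int = 0,
    coords: Optional[np.ndarray] = None,
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, float]:
    """Region-level model evaluation across subjects (or seeded replicates).

    For each (empirical, predicted) pair, computes the Pearson correlation
    between corresponding FC columns, standardizes it per region against a
    permutation null of the empirical FC, then runs a one-sample t-test
    versus zero across pairs. Returns a per-region table with the mean
    correlation, mean z, t statistic and ``-ln(p)``, plus the Bonferroni
    cutoff ``-ln(alpha/N)``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (empirical, predicted) pairs")
    emp0 = _as_matrix(pairs[0][0])
    n = emp0.shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(seed)
    z_rows, r_rows = [], []
    for fc_emp, fc_pred in pairs:
        emp = _as_matrix(fc_emp)
        pred = _as_matrix(fc_pred)
        r = _column_pearson(emp, pred)
        perms = _null_permutations(n, null, n_null, rng, coords)
        null_r = np.array([_column_pearson(emp[p][:, p], pred) for p in perms])
        sd = null_r.std(axis=0)
        sd[sd == 0] = np.nan
        z_rows.append((r - null_r.mean(axis=0)) / sd)
        r_rows.append(r)
    z_arr = np.array(z_rows)
    r_arr = np.array(r_rows)
    t_stat, p_val = stats.ttest_1samp(z_arr, popmean=0.0, axis=0)
    cutoff = bonferroni_cutoff(n, alpha)
    table = pd.DataFrame({
        "region": np.arange(n),
        "mean_pearson": r_arr.mean(axis=0),
        "mean_z": z_arr.mean(axis=0),
        "t": t_stat,
        "neg_log_p": -np.log(p_val),
    })
    table["significant"] = table["neg_log_p"] > cutoff
    return table, cutoff
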