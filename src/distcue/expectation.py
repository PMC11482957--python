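"""Cue-value weighting model of expectation generation.

Each of a cue's 10 values is weighted by its relative location in the cue's
distribution.  Values are rescaled to [0, 1] (division by the 100-point scale
range) and demeaned within the cue, giving deviations x_i.  Two weight terms
combine:

* a power term ``|x_i|^(k-1)`` (sum-normalized), with free parameter
  k in (0, 1000]: k > 1 over-weights outliers, k < 1 over-weights inliers,
  k = 1 weights all values equally;
* a logistic term ``1 / (1 + exp(-b x_i))`` with free parameter
  b in [-1000, 1000]: b < 0 over-weights values below the cue mean, b > 0
  values above it.

The two are summed and re-normalized to a probability vector, and the
expectation is the weighted sum of the original cue values — a convex
combination, hence always within the cue's range.  Parameters are fitted per
participant and modality by bounded nonlinear least squares with multi-start,
and tested at the group level with two-sided Wilcoxon signed-rank tests
(k vs 1, b vs 0) and cross-modality Spearman correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .design import MODALITIES, N_CUE_VALUES, cues_from_frame

K_BOUNDS = (1e-3, 1000.0)
B_BOUNDS = (-1000.0, 1000.0)
#: floor on |x_i| before exponentiation, avoids 0**0 and blow-ups at k < 1
X_EPS = 1e-6
#: multi-start initial values for the bounded least-squares fit
K_STARTS = (0.3, 1.0, 2.0, 5.0)
B_STARTS = (-8.0, 0.0, 8.0)


@dataclass(frozen=True)
class WeightParams:
    """Distortion parameters of the expectation model (one pair per
    participant x modality)."""

    k: float
    b: float

    def __post_init__(self):
        if not (K_BOUNDS[0] <= self.k <= K_BOUNDS[1]):
            raise ValueError(f"k={self.k} outside ({K_BOUNDS[0]}, {K_BOUNDS[1]}]")
        if not (B_BOUNDS[0] <= self.b <= B_BOUNDS[1]):
            raise ValueError(f"b={self.b} outside {list(B_BOUNDS)}")


def rescale_demean(values) -> np.ndarray:
    """Per-cue min-max rescaling of the 10 values to [0, 1], then demeaning.

    Values below the cue mean become negative, values above it positive, and
    every |x_i| <= 1.  A constant cue maps to ten zeros.  Rescaling within the
    cue (rather than by the global 100-point range) makes the weighting depend
    only on each value's relative location in its own distribution; the cue's
    absolute spread still reaches the expectation through the weighted sum of
    the original values.
    """
    v = np.asarray(values, dtype=float)
    mn = v.min(axis=-1, keepdims=True)
    mx = v.max(axis=-1, keepdims=True)
    rng_ = np.where(mx > mn, mx - mn, 1.0)
    x = (v - mn) / rng_
    return x - x.mean(axis=-1, keepdims=True)


def power_weights(x, k: float) -> np.ndarray:
    """Normalized power-term weights |x_i|^(k-1); equal weights at k = 1."""
    ax = np.maximum(np.abs(np.asarray(x, dtype=float)), X_EPS)
    with np.errstate(over="ignore"):
        raw = ax ** (k - 1.0)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    tot = raw.sum(axis=-1, keepdims=True)
    n = raw.shape[-1]
    return np.where(tot > 0, raw / np.where(tot > 0, tot, 1.0), 1.0 / n)


def logistic_weights(x, b: float) -> np.ndarray:
    """Logistic weights 1 / (1 + exp(-b x_i)), each in [0, 1]."""
    return expit(b * np.asarray(x, dtype=float))


def combine_weights(w_power, w_logistic) -> np.ndarray:
    """Sum the two weight terms and normalize to a probability vector."""
    s = np.asarray(w_power, dtype=float) + np.asarray(w_logistic, dtype=float)
    tot = s.sum(axis=-1, keepdims=True)
    assert np.all(tot > 0), "combined weights cannot sum to zero"
    return s / tot


def cue_weights(values, k: float, b: float) -> np.ndarray:
    """Combined normalized weights of a cue's 10 values (vectorizes over rows)."""
    x = rescale_demean(values)
    return combine_weights(power_weights(x, k), logistic_weights(x, b))


def predict_expectation(values, params: WeightParams | None = None, *,
                        k: float | None = None, b: float | None = None):
    """Model-predicted expectation: weighted sum of cue values, 0-100 scale.

    Accepts a single cue (length 10) or a (n, 10) matrix of cues.
    """
    if params is not None:
        k, b = params.k, params.b
    w = cue_weights(values, k, b)
    return (np.asarray(values, dtype=float) * w).sum(axis=-1)


@dataclass
class ExpectationFit:
    """Fitted distortion parameters and fit statistics for one
    participant x modality."""

    params: WeightParams
    rss: float
    pearson_r: float
    rmse: float
    n_trials: int
    converged: bool
    multistart_log: list = field(default_factory=list, repr=False)

    @property
    def k(self) -> float:
        return self.params.k

    @property
    def b(self) -> float:
        return self.params.b


def fit_expectation(
    cue_values: np.ndarray,
    ratings: np.ndarray,
    k_starts=K_STARTS,
    b_starts=B_STARTS,
    tol: float = 1e-10,
) -> ExpectationFit:
    """Fit (k, b) to one participant-modality block by bounded least squares.

    ``cue_values`` is (n_trials, 10); ``ratings`` the observed expectation
    ratings.  Every (k, b) start on the grid is optimized with the trust-region
    reflective method and the best final cost is kept.
    """
    V = np.asarray(cue_values, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if V.ndim != 2 or V.shape[1] != N_CUE_VALUES:
        raise ValueError("cue_values must be (n_trials, 10)")
    if V.shape[0] < 10:
        raise ValueError("at least 10 trials are required to fit (k, b)")
    if V.shape[0] != y.shape[0]:
        raise ValueError("cue_values and ratings length mismatch")

    x_mat = rescale_demean(V)

    def residuals(theta):
        k, b = theta
        w = combine_weights(power_weights(x_mat, k), logistic_weights(x_mat, b))
        return (V * w).sum(axis=1) - y

    lo = (K_BOUNDS[0], B_BOUNDS[0])
    hi = (K_BOUNDS[1], B_BOUNDS[1])
    best = None
    log = []
    for k0 in k_starts:
        for b0 in b_starts:
            try:
                sol = optimize.least_squares(
                    residuals, x0=[k0, b0], bounds=(lo, hi), method="trf",
                    ftol=tol, xtol=tol, gtol=tol,
                )
            except Exception as exc:  # pragma: no cover - optimizer edge
                log.append({"k0": k0, "b0": b0, "error": str(exc)})
                continue
            log.append({"k0": k0, "b0": b0, "cost": sol.cost,
                        "success": bool(sol.success)})
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise RuntimeError(f"no start converged; diagnostics: {log}")

    k, b = best.x
    pred = (V * cue_weights(V, k, b)).sum(axis=1)
    rss = float(np.sum((pred - y) ** 2))
    n = len(y)
    r = float(stats.pearsonr(pred, y)[0]) if np.std(pred) > 0 and np.std(y) > 0 else np.nan
    return ExpectationFit(
        params=WeightParams(k=float(k), b=float(b)),
        rss=rss,
        pearson_r=r,
        rmse=float(np.sqrt(rss / n)),
        n_trials=n,
        converged=True,
        multistart_log=log,
    )


def fit_expectation_table(
    trials: pd.DataFrame,
    rating_col: str = "expectation_rating",
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit the expectation model for every participant x modality in a trial
    table; returns one row per fit (participant_id, modality, k, b, rss, r,
    rmse, n_trials, converged)."""
    rows = []
    for (pid, mod), grp in trials.groupby(["participant_id", "modality"], sort=True):
        fit = fit_expectation(cues_from_frame(grp), grp[rating_col].to_numpy(),
                              **fit_kwargs)
        rows.append({"participant_id": pid, "modality": mod, "k": fit.k,
                     "b": fit.b, "rss": fit.rss, "r": fit.pearson_r,
                     "rmse": fit.rmse, "n_trials": fit.n_trials,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def _signed_rank(values: np.ndarray, null: float) -> dict:
    """Two-sided Wilcoxon signed-rank test of ``values`` against ``null``.

    Zero differences are dropped (Wilcoxon's convention); a degenerate sample
    with no nonzero differences returns statistic NaN and p = 1.
    """
    diffs = np.asarray(values, dtype=float) - null
    if np.all(diffs == 0):
        return {"statistic": float("nan"), "p_value": 1.0, "n_nonzero": 0}
    res = stats.wilcoxon(diffs, alternative="two-sided", zero_method="wilcox")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_nonzero": int(np.count_nonzero(diffs))}


def group_tests(fits: pd.DataFrame, min_participants: int = 6) -> dict:
    """Group-level nonparametric tests on fitted (k, b).

    Per modality: two-sided Wilcoxon signed-rank of k against 1 and b against
    0, with medians.  Across modalities: Spearman rank correlation of k (and
    b) between pain and vision over participants fitted in both.
    """
    out: dict = {"modalities": {}, "cross_modality": {}}
    for mod in MODALITIES:
        sub = fits[fits["modality"] == mod]
        if len(sub) < min_participants:
            raise ValueError(
                f"need >= {min_participants} participants per modality, "
                f"got {len(sub)} for {mod}")
        out["modalities"][mod] = {
            "n": int(len(sub)),
            "median_k": float(sub["k"].median()),
            "median_b": float(sub["b"].median()),
            "wilcoxon_k_vs_1": _signed_rank(sub["k"].to_numpy(), 1.0),
            "wilcoxon_b_vs_0": _signed_rank(sub["b"].to_numpy(), 0.0),
        }
    wide = fits.pivot(index="participant_id", columns="modality", values=["k", "b"])
    both = wide.dropna()
    for param in ("k", "b"):
        rho, p = stats.spearmanr(both[(param, "pain")], both[(param, "vision")])
        out["cross_modality"][param] = {
            "spearman_rho": float(rho), "p_value": float(p), "n": int(len(both))}
    return out
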