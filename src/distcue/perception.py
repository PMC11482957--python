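"""Five nested observer models of cued perception, fitting, and model
comparison.

All models scale each participant's calibrated stimulus response (the mean
rating for that modality x intensity from the stimulus-response task) by a
free factor s in [0, 5], one per modality.  The nested family is:

* M1 (baseline): rating(t) = intensity(t) * s  — cues ignored.
* M2 (expectation): rating(t) = (1 - w) * intensity(t) * s + w * expectation(t),
  one cue weight w in [0, 1] shared by both modalities.
* M3 (expectation learning): as M2 but w is updated trial-by-trial from the
  prediction error PE(t) = (rating(t) - expectation(t)) / 100 with learning
  rate alpha in [-1, 1]:  w(t+1) = clamp(w(t) - alpha * PE(t), 0, 1).
* M4: as M2 with modality-specific weights w_p, w_v.
* M5: as M3 with modality-specific weight and learning-rate streams.

Free-parameter counts are 2/3/4/4/6.  The expectation(t) term is produced by
the participant's fitted cue-weighting model (see :mod:`distcue.expectation`).
Models are fitted per participant by bounded least squares with multi-start
and compared with nested F tests (per participant and on the mean RSS across
participants) and AIC.

Conventions the family leaves open and this implementation fixes: the PE is
computed on the 0-1 scale (both terms divided by 100) so that alpha in
[-1, 1] yields stable trajectories; w is clamped to [0, 1] after every update;
rating(t) in the PE is the observed rating during fitting (one-step-ahead
prediction) and the realized simulated rating during simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5")
#: free parameters per model, in the optimizer's vector order
MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "M1": ("s_p", "s_v"),
    "M2": ("s_p", "s_v", "w"),
    "M3": ("s_p", "s_v", "w", "alpha"),
    "M4": ("s_p", "s_v", "w_p", "w_v"),
    "M5": ("s_p", "s_v", "w_p", "w_v", "alpha_p", "alpha_v"),
}
#: declared nesting graph (simple, complex)
NESTED_PAIRS = (("M1", "M2"), ("M2", "M3"), ("M2", "M4"), ("M4", "M5"),
                ("M3", "M5"))

S_BOUNDS = (0.0, 5.0)
W_BOUNDS = (0.0, 1.0)
ALPHA_BOUNDS = (-1.0, 1.0)
_PARAM_BOUNDS = {"s_p": S_BOUNDS, "s_v": S_BOUNDS, "w": W_BOUNDS,
                 "w_p": W_BOUNDS, "w_v": W_BOUNDS, "alpha": ALPHA_BOUNDS,
                 "alpha_p": ALPHA_BOUNDS, "alpha_v": ALPHA_BOUNDS}
#: RSS floor inside the AIC log, keeps AIC finite on (near-)perfect fits
_RSS_FLOOR = 1e-10


class CalibrationTable:
    """Per-participant mean calibration rating by modality x intensity level.

    Built from the stimulus-response task; supplies the ``intensity(t)`` term
    of every observer model.  Warns (does not fail) if cell means are not
    nondecreasing in intensity within a modality.
    """

    def __init__(self, table: dict[tuple[str, int], float]):
        self._table = dict(table)
        for (mod, lvl), val in self._table.items():
            if not (0.0 <= val <= 100.0):
                raise ValueError(f"calibration mean {val} outside [0, 100]")
        self.monotone = True
        for mod in {m for m, _ in self._table}:
            lvls = sorted(l for m, l in self._table if m == mod)
            vals = [self._table[(mod, l)] for l in lvls]
            if any(b < a for a, b in zip(vals, vals[1:])):
                self.monotone = False
                import warnings
                warnings.warn(f"calibration means not nondecreasing for {mod}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   value_col: str = "mean_rating") -> "CalibrationTable":
        if df.duplicated(["modality", "intensity_level"]).any():
            raise ValueError("duplicate calibration cells")
        return cls({(r["modality"], int(r["intensity_level"])): float(r[value_col])
                    for _, r in df.iterrows()})

    def lookup(self, modality, intensity_level) -> np.ndarray:
        mods = np.atleast_1d(modality)
        lvls = np.atleast_1d(intensity_level)
        out = np.empty(len(mods), dtype=float)
        for i, (m, l) in enumerate(zip(mods, lvls)):
            key = (m, int(l))
            if key not in self._table:
                raise KeyError(f"no calibration cell for {key}")
            out[i] = self._table[key]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"modality": m, "intensity_level": l, "mean_rating": v}
             for (m, l), v in sorted(self._table.items())])


@dataclass(frozen=True)
class PerceptionParams:
    """Observer-model parameters; exactly the free parameters of ``model_id``
    are set."""

    model_id: str
    s_p: float
    s_v: float
    w: float | None = None
    w_p: float | None = None
    w_v: float | None = None
    alpha: float | None = None
    alpha_p: float | None = None
    alpha_v: float | None = None

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}; valid: {MODEL_IDS}")
        names = MODEL_PARAM_NAMES[self.model_id]
        for name in ("s_p", "s_v", "w", "w_p", "w_v", "alpha", "alpha_p",
                     "alpha_v"):
            val = getattr(self, name)
            if name in names:
                if val is None:
                    raise ValueError(f"{self.model_id} requires {name}")
                lo, hi = _PARAM_BOUNDS[name]
                if not (lo <= val <= hi):
                    raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
            elif val is not None:
                raise ValueError(f"{self.model_id} does not take {name}")

    @property
    def n_free(self) -> int:
        return len(MODEL_PARAM_NAMES[self.model_id])

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MODEL_PARAM_NAMES[self.model_id]])

    @classmethod
    def from_vector(cls, model_id: str, theta) -> "PerceptionParams":
        names = MODEL_PARAM_NAMES[model_id]
        if len(theta) != len(names):
            raise ValueError(f"{model_id} takes {len(names)} parameters")
        return cls(model_id=model_id, **dict(zip(names, map(float, theta))))


def n_free_params(model_id: str) -> int:
    """Number of free parameters of an observer model (2/3/4/4/6)."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    return len(MODEL_PARAM_NAMES[model_id])


def run_model(
    params: PerceptionParams,
    intensity: np.ndarray,
    is_pain: np.ndarray,
    expectation: np.ndarray | None,
    ratings: np.ndarray | None = None,
    mode: str = "fit",
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Run an observer model over trials in presentation order.

    Returns ``(predictions, w_trajectory, realized)`` where ``w_trajectory``
    is the per-trial cue weight actually applied (None for M1) and
    ``realized`` the noisy clipped ratings in simulate mode (None in fit
    mode).  In fit mode the learning models consume the observed ``ratings``
    for their prediction errors (one-step-ahead prediction).
    """
    if mode not in ("fit", "simulate"):
        raise ValueError("mode must be 'fit' or 'simulate'")
    m = params.model_id
    intensity = np.asarray(intensity, dtype=float)
    is_pain = np.asarray(is_pain, dtype=bool)
    n = len(intensity)
    s = np.where(is_pain, params.s_p, params.s_v)
    base = intensity * s
    if m != "M1" and expectation is None:
        raise ValueError(f"{m} requires per-trial cue-based expectations")

    learning = m in ("M3", "M5")
    if not learning:
        if m == "M1":
            pred = base
            w_traj = None
        else:
            w = np.full(n, params.w) if m == "M2" else np.where(
                is_pain, params.w_p, params.w_v)
            pred = (1.0 - w) * base + w * np.asarray(expectation, dtype=float)
            w_traj = w
    else:
        if mode == "fit":
            if ratings is None or np.any(~np.isfinite(np.asarray(ratings, dtype=float))):
                raise ValueError("fit mode requires observed ratings on every trial")
            ratings = np.asarray(ratings, dtype=float)
        expectation = np.asarray(expectation, dtype=float)
        if m == "M3":
            w_state = {True: params.w, False: params.w}
            alpha = {True: params.alpha, False: params.alpha}
            shared = True
        else:
            w_state = {True: params.w_p, False: params.w_v}
            alpha = {True: params.alpha_p, False: params.alpha_v}
            shared = False
        pred = np.empty(n)
        w_traj = np.empty(n)
        realized = np.empty(n)
        for t in range(n):
            p = bool(is_pain[t])
            w = w_state[p]
            w_traj[t] = w
            pred[t] = (1.0 - w) * base[t] + w * expectation[t]
            if mode == "fit":
                outcome = ratings[t]
            else:
                noisy = pred[t] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                outcome = float(np.clip(noisy, 0.0, 100.0))
                realized[t] = outcome
            pe = (outcome - expectation[t]) / 100.0
            new_w = min(1.0, max(0.0, w - alpha[p] * pe))
            if shared:
                w_state[True] = w_state[False] = new_w
            else:
                w_state[p] = new_w
        if mode == "simulate":
            return pred, w_traj, realized
        return pred, w_traj, None

    if mode == "simulate":
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        realized = np.clip(pred + noise, 0.0, 100.0)
        return pred, w_traj, realized
    return pred, w_traj, None


def predict_trial(params: PerceptionParams, intensity: float, is_pain: bool,
                  expectation: float | None = None,
                  w_current: float | None = None) -> float:
    """Single-trial prediction; learning models take the current state's w."""
    m = params.model_id
    s = params.s_p if is_pain else params.s_v
    if m == "M1":
        return intensity * s
    if expectation is None:
        raise ValueError(f"{m} requires a cue-based expectation")
    if m == "M2":
        w = params.w
    elif m == "M4":
        w = params.w_p if is_pain else params.w_v
    else:
        if w_current is None:
            w = params.w if m == "M3" else (params.w_p if is_pain else params.w_v)
        else:
            w = w_current
    return (1.0 - w) * intensity * s + w * expectation


@dataclass
class PerceptionFit:
    """One fitted observer model for one participant."""

    params: PerceptionParams
    rss: float
    n_trials: int
    predictions: np.ndarray = field(repr=False)
    w_trajectory: np.ndarray | None = field(repr=False)
    aic: float = field(init=False)
    multistart_log: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.aic = aic_ols(self.rss, self.n_trials, self.params.n_free)

    @property
    def model_id(self) -> str:
        return self.params.model_id


def aic_ols(rss: float, n: int, p: int) -> float:
    """Gaussian-OLS Akaike Information Criterion, n ln(RSS/n) + 2p.

    The RSS is floored at a machine-level constant so the criterion stays
    finite on numerically perfect fits.
    """
    return n * math.log(max(rss, _RSS_FLOOR) / n) + 2 * p


def _default_starts(model_id: str) -> list[np.ndarray]:
    s0 = [1.0, 1.0]
    if model_id == "M1":
        return [np.array([a, b]) for a in (0.5, 1.5) for b in (0.5, 1.5)]
    if model_id == "M2":
        return [np.array(s0 + [w]) for w in (0.1, 0.5, 0.9)]
    if model_id == "M3":
        return [np.array(s0 + [w, a]) for w in (0.2, 0.8)
                for a in (-0.25, 0.0, 0.25)]
    if model_id == "M4":
        return [np.array(s0 + [wp, wv]) for wp in (0.2, 0.8) for wv in (0.2, 0.8)]
    return [np.array(s0 + [wp, wv, a, a]) for wp in (0.2, 0.8)
            for wv in (0.2, 0.8) for a in (-0.25, 0.0, 0.25)]


def _order_trials(trials: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("block", "mini_block", "trial") if c in trials.columns]
    return trials.sort_values(cols, kind="stable") if cols else trials


def fit_perception(
    trials: pd.DataFrame,
    model_id: str,
    calibration: CalibrationTable,
    expectation_col: str = "expectation",
    rating_col: str = "perception_rating",
    starts: list | None = None,
    tol: float = 1e-10,
) -> PerceptionFit:
    """Fit one observer model to one participant's cued-perception trials.

    Trials are sorted into presentation order (block / mini_block / trial)
    before the learning dynamics run.  Multi-start bounded least squares; the
    best converged start is kept.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; valid: {MODEL_IDS}")
    trials = _order_trials(trials)
    p = n_free_params(model_id)
    if len(trials) < p + 2:
        raise ValueError(f"{model_id} needs at least {p + 2} trials")
    is_pain = (trials["modality"] == "pain").to_numpy()
    intensity = calibration.lookup(trials["modality"].to_numpy(),
                                   trials["intensity_level"].to_numpy())
    y = trials[rating_col].to_numpy(dtype=float)
    expectation = (trials[expectation_col].to_numpy(dtype=float)
                   if model_id != "M1" else None)

    names = MODEL_PARAM_NAMES[model_id]
    lo = np.array([_PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([_PARAM_BOUNDS[n][1] for n in names])

    def residuals(theta):
        params = PerceptionParams.from_vector(model_id, np.clip(theta, lo, hi))
        pred, _, _ = run_model(params, intensity, is_pain, expectation,
                               ratings=y, mode="fit")
        return pred - y

    best = None
    log = []
    for x0 in (starts if starts is not None else _default_starts(model_id)):
        try:
            sol = optimize.least_squares(residuals, x0=np.asarray(x0, dtype=float),
                                         bounds=(lo, hi), method="trf",
                                         ftol=tol, xtol=tol, gtol=tol)
        except Exception as exc:  # pragma: no cover
            log.append({"x0": list(x0), "error": str(exc)})
            continue
        log.append({"x0": list(np.round(x0, 3)), "cost": sol.cost,
                    "success": bool(sol.success)})
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(f"no start converged for {model_id}; diagnostics: {log}")

    params = PerceptionParams.from_vector(model_id, best.x)
    pred, w_traj, _ = run_model(params, intensity, is_pain, expectation,
                                ratings=y, mode="fit")
    rss = float(np.sum((pred - y) ** 2))
    return PerceptionFit(params=params, rss=rss, n_trials=len(y),
                         predictions=pred, w_trajectory=w_traj,
                         multistart_log=log)


def _seeded_starts(model_id: str, fits: dict[str, PerceptionFit]) -> list[np.ndarray]:
    """Default starts plus warm starts embedding already-fitted nested models,
    which enforces the nesting inequality RSS_complex <= RSS_simple."""
    starts = _default_starts(model_id)
    if model_id == "M2" and "M1" in fits:
        t = fits["M1"].params
        starts.append(np.array([t.s_p, t.s_v, 0.0]))
    if model_id == "M3" and "M2" in fits:
        t = fits["M2"].params
        starts = [np.array([t.s_p, t.s_v, t.w, a]) for a in (-0.25, 0.0, 0.25)]
    if model_id == "M4" and "M2" in fits:
        t = fits["M2"].params
        starts.append(np.array([t.s_p, t.s_v, t.w, t.w]))
    if model_id == "M5":
        starts = []
        if "M4" in fits:
            t = fits["M4"].params
            starts += [np.array([t.s_p, t.s_v, t.w_p, t.w_v, a, a])
                       for a in (-0.25, 0.0, 0.25)]
        if "M3" in fits:
            t = fits["M3"].params
            starts.append(np.array([t.s_p, t.s_v, t.w, t.w, t.alpha, t.alpha]))
        if not starts:
            starts = _default_starts("M5")
    return starts


def fit_all_models(
    trials: pd.DataFrame,
    calibration: CalibrationTable,
    model_ids=MODEL_IDS,
    **kwargs,
) -> dict[str, PerceptionFit]:
    """Fit the requested observer models for one participant, simple to
    complex, warm-starting each model from its nested parents."""
    fits: dict[str, PerceptionFit] = {}
    for m in MODEL_IDS:
        if m not in model_ids:
            continue
        fits[m] = fit_perception(trials, m, calibration,
                                 starts=_seeded_starts(m, fits), **kwargs)
    return fits


def compare_nested(fit_simple: PerceptionFit, fit_complex: PerceptionFit,
                   n: int | None = None) -> dict:
    """Nested F test between two observer-model fits on the same trials.

    F = ((RSS_s - RSS_c) / (p_c - p_s)) / (RSS_c / (n - p_c)); a negative
    numerator (possible only through optimizer noise) is floored at zero.
    """
    pair = (fit_simple.model_id, fit_complex.model_id)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"{pair} is not a declared nested pair; valid: {NESTED_PAIRS}")
    if n is None:
        if fit_simple.n_trials != fit_complex.n_trials:
            raise ValueError("fits must share the same trials")
        n = fit_simple.n_trials
    p_s, p_c = fit_simple.params.n_free, fit_complex.params.n_free
    df1, df2 = p_c - p_s, n - p_c
    num = max(fit_simple.rss - fit_complex.rss, 0.0) / df1
    den = fit_complex.rss / df2
    f = num / den if den > 0 else (0.0 if num == 0 else float("inf"))
    return {"pair": pair, "F": float(f), "df1": df1, "df2": df2,
            "p_value": float(stats.f.sf(f, df1, df2))}


def group_compare(fits_by_participant: dict[object, dict[str, PerceptionFit]]) -> dict:
    """Group-level model comparison across participants.

    For each declared nested pair: per-participant F tests plus a group F
    computed from the mean RSS across participants, with n taken as the mean
    trial count per participant (a documented convention; the participant-
    level tests carry the inferential weight).  AIC is summed across
    participants per model; winners are reported per criterion.
    """
    pids = sorted(fits_by_participant, key=str)
    models = sorted({m for f in fits_by_participant.values() for m in f})
    for pid in pids:
        if sorted(fits_by_participant[pid]) != models:
            raise ValueError("all participants must carry the same fitted models")
    mean_rss = {m: float(np.mean([fits_by_participant[p][m].rss for p in pids]))
                for m in models}
    sum_aic = {m: float(np.sum([fits_by_participant[p][m].aic for p in pids]))
               for m in models}
    mean_n = float(np.mean([fits_by_participant[pids[0]][models[0]].n_trials
                            for _ in (0,)])) if pids else 0.0
    mean_n = float(np.mean([fits_by_participant[p][models[0]].n_trials
                            for p in pids]))

    report: dict = {"models": models, "mean_rss": mean_rss,
                    "summed_aic": sum_aic, "participants": pids,
                    "mean_n_trials": mean_n, "pairs": {}}
    for simple, complex_ in NESTED_PAIRS:
        if simple not in models or complex_ not in models:
            continue
        per_part = [compare_nested(fits_by_participant[p][simple],
                                   fits_by_participant[p][complex_])
                    for p in pids]
        p_s = n_free_params(simple)
        p_c = n_free_params(complex_)
        df1, df2 = p_c - p_s, max(int(round(mean_n)) - p_c, 1)
        num = max(mean_rss[simple] - mean_rss[complex_], 0.0) / df1
        den = mean_rss[complex_] / df2
        f = num / den if den > 0 else 0.0
        report["pairs"][f"{simple}_vs_{complex_}"] = {
            "group_F": float(f), "df1": df1, "df2": df2,
            "group_p": float(stats.f.sf(f, df1, df2)),
            "participant_F": [r["F"] for r in per_part],
            "participant_p": [r["p_value"] for r in per_part],
            "n_significant": int(sum(r["p_value"] < 0.05 for r in per_part)),
        }
    report["aic_winner"] = min(sum_aic, key=sum_aic.get)
    return report


def fits_to_frame(fits_by_participant: dict[object, dict[str, PerceptionFit]]
                  ) -> pd.DataFrame:
    """Flatten per-participant observer-model fits to one row per fit."""
    rows = []
    for pid, fits in fits_by_participant.items():
        for m, fit in fits.items():
            row = {"participant_id": pid, "model_id": m, "rss": fit.rss,
                   "aic": fit.aic, "n_trials": fit.n_trials}
            for name in MODEL_PARAM_NAMES[m]:
                row[name] = getattr(fit.params, name)
            rows.append(row)
    return pd.DataFrame(rows)
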