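"""Synthetic participants for parameter-recovery and model-identification
studies.

The original study's trial-level data are not deposited, so the package
exercises its models end-to-end on simulated cohorts: each synthetic
participant carries known ("truth") parameters — per-modality cue-weighting
distortions (k, b), an observer model with its parameters, calibration
slope/intercept, rating-noise SD and a response-time law — and completes the
three tasks with the study's exact factorial designs.  Ratings are the
generating model's prediction plus additive Gaussian noise, clipped to the
0-100 scale.  Response times exist only to exercise the trial-exclusion rule
(kept window 0.2-4.5 s, strict inequalities excluded).

Truth-sampling defaults are centred on the fitted group medians reported for
the original cohort (k: 1.66 pain / 1.47 vision; b: -1.64 pain / 0.16 vision)
with documented spreads, and a rating-noise SD of 6 VAS units, which places
model fits in the observed range (r ~ 0.94, RMSE ~ 6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import design as dz
from . import expectation as ex
from . import perception as pc

RT_MIN, RT_MAX = 0.2, 4.5  # kept window, seconds (closed interval)


@dataclass
class CohortConfig:
    """Truth-sampling distributions and study dimensions for one synthetic
    cohort.  All defaults are serialized with every run."""

    n_participants: int = 45
    seed: int | None = None
    # cue-weighting truth: k log-normal about the group medians, b normal
    k_center: dict = field(default_factory=lambda: {"pain": 1.66, "vision": 1.47})
    k_log_sd: float = 1.0
    b_center: dict = field(default_factory=lambda: {"pain": -1.64, "vision": 0.16})
    b_sd: float = 2.5
    # additive Gaussian rating noise, VAS units
    noise_sd: float = 6.0
    calib_noise_sd: float = 6.0
    # calibration line: mean rating = intercept + slope * intensity level
    calib_intercept_mean: float = 15.0
    calib_intercept_sd: float = 5.0
    calib_slope_mean: float = 13.0
    calib_slope_sd: float = 2.0
    # observer-model truth
    perception_model: str = "M2"
    s_mean: float = 1.0
    s_sd: float = 0.15
    w_range: tuple = (0.2, 0.8)
    alpha_magnitude: tuple = (0.1, 0.4)
    # response-time law: log-normal inliers plus an out-of-window mixture
    rt_median: float = 0.9
    rt_log_sd: float = 0.35
    rt_outlier_fraction: float = 0.05

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("a cohort needs at least 2 participants")
        if self.noise_sd <= 0 or self.calib_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if self.perception_model not in pc.MODEL_IDS:
            raise ValueError(f"unknown perception model {self.perception_model!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParticipantTruth:
    """Generative parameters of one synthetic participant."""

    participant_id: str
    k: dict
    b: dict
    perception: pc.PerceptionParams
    noise_sd: float
    calib_noise_sd: float
    calib_intercept: dict
    calib_slope: dict
    rt_median: float
    rt_log_sd: float
    rt_outlier_fraction: float

    def expectation_params(self, modality: str) -> ex.WeightParams:
        return ex.WeightParams(k=self.k[modality], b=self.b[modality])


def _sample_perception_params(config: CohortConfig, rng: np.random.Generator
                              ) -> pc.PerceptionParams:
    m = config.perception_model
    s = lambda: float(np.clip(rng.normal(config.s_mean, config.s_sd), 0.2, 3.0))
    w = lambda: float(rng.uniform(*config.w_range))
    a = lambda: float(rng.uniform(*config.alpha_magnitude) * rng.choice([-1, 1]))
    kw: dict = {"s_p": s(), "s_v": s()}
    if m == "M2":
        kw["w"] = w()
    elif m == "M3":
        kw["w"], kw["alpha"] = w(), a()
    elif m == "M4":
        kw["w_p"], kw["w_v"] = w(), w()
    elif m == "M5":
        kw.update(w_p=w(), w_v=w(), alpha_p=a(), alpha_v=a())
    return pc.PerceptionParams(model_id=m, **kw)


def sample_truths(config: CohortConfig, rng: np.random.Generator
                  ) -> list[ParticipantTruth]:
    """Draw one ParticipantTruth per participant from the config's
    truth-sampling distributions."""
    truths = []
    for i in range(config.n_participants):
        k = {m: float(np.clip(config.k_center[m] * rng.lognormal(0.0, config.k_log_sd),
                              ex.K_BOUNDS[0], ex.K_BOUNDS[1]))
             for m in dz.MODALITIES}
        b = {m: float(np.clip(rng.normal(config.b_center[m], config.b_sd),
                              ex.B_BOUNDS[0], ex.B_BOUNDS[1]))
             for m in dz.MODALITIES}
        truths.append(ParticipantTruth(
            participant_id=f"sub-{i + 1:03d}",
            k=k, b=b,
            perception=_sample_perception_params(config, rng),
            noise_sd=config.noise_sd,
            calib_noise_sd=config.calib_noise_sd,
            calib_intercept={m: float(rng.normal(config.calib_intercept_mean,
                                                 config.calib_intercept_sd))
                             for m in dz.MODALITIES},
            calib_slope={m: float(max(rng.normal(config.calib_slope_mean,
                                                 config.calib_slope_sd), 1.0))
                         for m in dz.MODALITIES},
            rt_median=config.rt_median,
            rt_log_sd=config.rt_log_sd,
            rt_outlier_fraction=config.rt_outlier_fraction,
        ))
    return truths


def truths_to_frame(truths: list[ParticipantTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {"participant_id": t.participant_id,
               "k_pain": t.k["pain"], "k_vision": t.k["vision"],
               "b_pain": t.b["pain"], "b_vision": t.b["vision"],
               "model_id": t.perception.model_id,
               "noise_sd": t.noise_sd}
        for name in pc.MODEL_PARAM_NAMES[t.perception.model_id]:
            row[f"true_{name}"] = getattr(t.perception, name)
        rows.append(row)
    return pd.DataFrame(rows)


def _response_times(truth: ParticipantTruth, n: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """Log-normal inlier RTs (truncated into the kept window) with an
    out-of-window outlier mixture."""
    rt = np.clip(rng.lognormal(math.log(truth.rt_median), truth.rt_log_sd, size=n),
                 RT_MIN + 0.01, RT_MAX - 0.01)
    out = rng.random(n) < truth.rt_outlier_fraction
    fast = rng.random(n) < 0.5
    rt[out & fast] = rng.uniform(0.03, RT_MIN - 1e-3, size=int(np.sum(out & fast)))
    rt[out & ~fast] = rng.uniform(RT_MAX + 1e-3, RT_MAX + 1.5,
                                  size=int(np.sum(out & ~fast)))
    return rt


def simulate_calibration(truth: ParticipantTruth, design: pd.DataFrame,
                         rng: np.random.Generator
                         ) -> tuple[pc.CalibrationTable, pd.DataFrame]:
    """Simulate the stimulus-response task and aggregate cell means.

    Trial rating = intercept + slope * intensity level + Gaussian noise,
    clipped to the scale, so cell means rise with stimulus intensity.
    """
    trials = design.copy()
    lvl = trials["intensity_level"].to_numpy(dtype=float)
    mean = np.array([truth.calib_intercept[m] for m in trials["modality"]]) + \
        np.array([truth.calib_slope[m] for m in trials["modality"]]) * lvl
    rating = np.clip(mean + rng.normal(0.0, truth.calib_noise_sd, len(trials)),
                     0.0, 100.0)
    trials["rating"] = rating
    trials["response_time_s"] = _response_times(truth, len(trials), rng)
    trials.insert(0, "participant_id", truth.participant_id)
    cells = (trials.groupby(["modality", "intensity_level"])["rating"]
             .mean().reset_index().rename(columns={"rating": "mean_rating"}))
    cells["intensity_level"] = cells["intensity_level"].astype(int)
    cells.insert(0, "participant_id", truth.participant_id)
    return pc.CalibrationTable.from_frame(cells), trials


def simulate_expectation_task(truth: ParticipantTruth, design_cues: pd.DataFrame,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the expectation task from the cue-weighting model."""
    trials = design_cues.copy()
    V = dz.cues_from_frame(trials)
    pred = np.empty(len(trials))
    for mod in dz.MODALITIES:
        mask = (trials["modality"] == mod).to_numpy()
        if mask.any():
            pred[mask] = ex.predict_expectation(V[mask], truth.expectation_params(mod))
    trials["expectation_rating"] = np.clip(
        pred + rng.normal(0.0, truth.noise_sd, len(trials)), 0.0, 100.0)
    trials["response_time_s"] = _response_times(truth, len(trials), rng)
    trials.insert(0, "participant_id", truth.participant_id)
    return trials


def simulate_perception_task(truth: ParticipantTruth, design_cues: pd.DataFrame,
                             calibration: pc.CalibrationTable,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the cued-perception task under the participant's observer
    model, propagating learned cue weights over realized noisy ratings."""
    trials = pc._order_trials(design_cues).copy()
    V = dz.cues_from_frame(trials)
    expect = np.empty(len(trials))
    for mod in dz.MODALITIES:
        mask = (trials["modality"] == mod).to_numpy()
        if mask.any():
            expect[mask] = ex.predict_expectation(V[mask], truth.expectation_params(mod))
    is_pain = (trials["modality"] == "pain").to_numpy()
    intensity = calibration.lookup(trials["modality"].to_numpy(),
                                   trials["intensity_level"].to_numpy())
    pred, w_traj, realized = pc.run_model(
        truth.perception, intensity, is_pain, expect, mode="simulate",
        noise_sd=truth.noise_sd, rng=rng)
    trials["expectation_true"] = expect
    trials["model_prediction"] = pred
    trials["perception_rating"] = realized
    if w_traj is not None:
        trials["w_applied"] = w_traj
    trials["response_time_s"] = _response_times(truth, len(trials), rng)
    trials.insert(0, "participant_id", truth.participant_id)
    return trials


def simulate_participant(truth: ParticipantTruth, rng: np.random.Generator,
                         modality_order: str = "pain_first") -> dict:
    """All three tasks for one participant: fresh design randomization, fresh
    cues, simulated ratings and response times."""
    sr_design = dz.enumerate_design("stimulus_response", rng, modality_order)
    calib, calib_trials = simulate_calibration(truth, sr_design, rng)
    exp_design = dz.generate_cues_for_design(
        dz.enumerate_design("expectation", rng, modality_order), rng)
    exp_trials = simulate_expectation_task(truth, exp_design, rng)
    per_design = dz.generate_cues_for_design(
        dz.enumerate_design("cued_perception", rng, modality_order), rng)
    per_trials = simulate_perception_task(truth, per_design, calib, rng)
    return {"calibration": calib, "calibration_trials": calib_trials,
            "expectation_trials": exp_trials, "perception_trials": per_trials}


def simulate_cohort(config: CohortConfig,
                    rng: np.random.Generator | int | None = None) -> dict:
    """Simulate a full cohort; same seed gives a byte-identical cohort."""
    if rng is None:
        rng = config.seed
    rng = np.random.default_rng(rng)
    truths = sample_truths(config, rng)
    calib_tables: dict[str, pc.CalibrationTable] = {}
    parts = {"calibration_trials": [], "expectation_trials": [],
             "perception_trials": []}
    for i, truth in enumerate(truths):
        order = "pain_first" if i % 2 == 0 else "vision_first"
        sim = simulate_participant(truth, rng, modality_order=order)
        calib_tables[truth.participant_id] = sim["calibration"]
        for key in parts:
            parts[key].append(sim[key])
    return {
        "config": config,
        "truths": truths,
        "truth_frame": truths_to_frame(truths),
        "calibration_tables": calib_tables,
        **{k: pd.concat(v, ignore_index=True) for k, v in parts.items()},
    }


def exclude_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials with response time < 0.2 s (too fast to be deliberate) or
    > 4.5 s (rating not completed in the rating period); boundary values are
    kept.  Returns (kept trials, per-participant exclusion log)."""
    if "response_time_s" not in trials.columns:
        raise ValueError("trials lack a response_time_s column")
    rt = trials["response_time_s"].to_numpy(dtype=float)
    fast = rt < RT_MIN
    slow = rt > RT_MAX
    kept = trials.loc[~(fast | slow)].copy()
    log = (trials.assign(excluded_fast=fast, excluded_slow=slow)
           .groupby("participant_id")[["excluded_fast", "excluded_slow"]]
           .sum().astype(int).reset_index())
    log["n_total"] = trials.groupby("participant_id").size().values
    log["n_kept"] = log["n_total"] - log["excluded_fast"] - log["excluded_slow"]
    return kept, log


# ---------------------------------------------------------------------------
# analysis over a simulated (or ingested) cohort


def attach_fitted_expectations(trials: pd.DataFrame, fits: pd.DataFrame,
                               col: str = "expectation") -> pd.DataFrame:
    """Add the cue-based expectation from each participant's fitted (k, b)
    to every trial (the input the observer models consume)."""
    out = trials.copy()
    V = dz.cues_from_frame(out)
    vals = np.full(len(out), np.nan)
    lut = {(r["participant_id"], r["modality"]): (r["k"], r["b"])
           for _, r in fits.iterrows()}
    for (pid, mod), grp in out.groupby(["participant_id", "modality"]):
        k, b = lut[(pid, mod)]
        idx = out.index.get_indexer(grp.index)
        vals[idx] = ex.predict_expectation(V[idx], k=k, b=b)
    out[col] = vals
    return out


def _recovery_stats(true: np.ndarray, recovered: np.ndarray) -> dict:
    err = recovered - true
    rho = stats.spearmanr(true, recovered)[0] if len(true) > 2 else float("nan")
    return {"spearman": float(rho), "bias": float(np.mean(err)),
            "rmse": float(np.sqrt(np.mean(err**2))), "n": int(len(true))}


def analyze_cohort(cohort: dict, fit_model_ids=pc.MODEL_IDS,
                   use_true_expectations: bool = False) -> dict:
    """Run the full analysis pipeline on a simulated cohort.

    Stages: RT-based exclusion -> expectation-model fits per participant x
    modality -> group tests -> per-trial expectations from the fitted (k, b)
    (or the generating truth, for sensitivity analyses) -> observer-model fits
    M1-M5 -> nested comparison report.
    """
    exp_kept, exp_log = exclude_trials(cohort["expectation_trials"])
    per_kept, per_log = exclude_trials(cohort["perception_trials"])
    exp_fits = ex.fit_expectation_table(exp_kept)
    tests = ex.group_tests(exp_fits)
    if use_true_expectations:
        per_kept = per_kept.rename(columns={"expectation_true": "expectation"})
    else:
        per_kept = attach_fitted_expectations(per_kept, exp_fits)
    fits_by_participant = {}
    for pid, grp in per_kept.groupby("participant_id"):
        fits_by_participant[pid] = pc.fit_all_models(
            grp, cohort["calibration_tables"][pid], model_ids=fit_model_ids)
    comparison = pc.group_compare(fits_by_participant)
    return {"expectation_fits": exp_fits, "group_tests": tests,
            "perception_fits": fits_by_participant,
            "perception_fit_frame": pc.fits_to_frame(fits_by_participant),
            "comparison": comparison,
            "exclusion_log": pd.concat([exp_log.assign(task="expectation"),
                                        per_log.assign(task="cued_perception")],
                                       ignore_index=True)}


def expectation_recovery(truth_frame: pd.DataFrame,
                         exp_fits: pd.DataFrame) -> dict:
    """True-vs-recovered agreement for k and b, per modality."""
    out = {}
    for mod in dz.MODALITIES:
        sub = exp_fits[exp_fits["modality"] == mod].merge(
            truth_frame, on="participant_id")
        out[mod] = {
            "k": _recovery_stats(sub[f"k_{mod}"].to_numpy(), sub["k"].to_numpy()),
            "b": _recovery_stats(sub[f"b_{mod}"].to_numpy(), sub["b"].to_numpy()),
        }
    return out


def perception_recovery(truths: list[ParticipantTruth],
                        fits_by_participant: dict) -> dict:
    """True-vs-recovered agreement for the generating observer model's own
    parameters (each participant's fit of their true model)."""
    by_param: dict[str, dict[str, list]] = {}
    for t in truths:
        fit = fits_by_participant[t.participant_id].get(t.perception.model_id)
        if fit is None:
            continue
        for name in pc.MODEL_PARAM_NAMES[t.perception.model_id]:
            d = by_param.setdefault(name, {"true": [], "recovered": []})
            d["true"].append(getattr(t.perception, name))
            d["recovered"].append(getattr(fit.params, name))
    return {name: _recovery_stats(np.array(d["true"]), np.array(d["recovered"]))
            for name, d in by_param.items()}


def recovery_study(config: CohortConfig,
                   rng: np.random.Generator | int | None = None,
                   fit_model_ids=pc.MODEL_IDS,
                   use_true_expectations: bool = False) -> dict:
    """Full generate -> exclude -> fit -> compare pipeline with true-vs-
    recovered summaries; fully seeded and reproducible."""
    cohort = simulate_cohort(config, rng)
    analysis = analyze_cohort(cohort, fit_model_ids=fit_model_ids,
                              use_true_expectations=use_true_expectations)
    winners = {pid: min(fits, key=lambda m: fits[m].aic)
               for pid, fits in analysis["perception_fits"].items()}
    return {
        "config": config.to_dict(),
        "expectation_recovery": expectation_recovery(
            cohort["truth_frame"], analysis["expectation_fits"]),
        "group_tests": analysis["group_tests"],
        "perception_recovery": perception_recovery(
            cohort["truths"], analysis["perception_fits"]),
        "comparison": analysis["comparison"],
        "participant_aic_winners": winners,
        "generating_model": config.perception_model,
        "cohort_aic_winner": analysis["comparison"]["aic_winner"],
    }


def identification_study(base_config: CohortConfig,
                         rng: np.random.Generator | int | None = None,
                         generators=pc.MODEL_IDS,
                         n_cohorts: int = 3) -> dict:
    """Model-identification confusion matrix: simulate cohorts from each
    generating observer model, fit all five, record the summed-AIC winner."""
    rng = np.random.default_rng(rng)
    confusion = {g: {m: 0 for m in pc.MODEL_IDS} for g in generators}
    for gen in generators:
        for _ in range(n_cohorts):
            cfg = CohortConfig(**{**base_config.to_dict(),
                                  "perception_model": gen, "seed": None})
            report = recovery_study(cfg, rng)
            confusion[gen][report["cohort_aic_winner"]] += 1
    return {"confusion": confusion, "n_cohorts_per_generator": n_cohorts,
            "diagonal_fraction": {
                g: confusion[g][g] / n_cohorts for g in generators}}
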