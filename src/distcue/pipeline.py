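"""Pipeline orchestration and regressor-coding export.

The mixed-effects regressions users run downstream are standard; this module
guarantees only the study's coding conventions — binary factors coded +1/-1
(pain / high level = 1), two skewness dummies against the symmetric
reference, numeric covariates z-scored within the stated scope — plus a
seeded, manifest-tracked stage runner over the simulation and fitting stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort as ch
from . import design as dz
from . import expectation as ex
from . import perception as pc

STAGES = ("simulate", "exclude", "fit_expectation", "group_tests",
          "fit_perception", "compare", "export")

_BINARY_CODES = {
    "modality": {"pain": 1, "vision": -1},
    "cue_sd_level": {max(dz.CUE_SDS): 1, min(dz.CUE_SDS): -1},
    "intensity_level": {max(dz.PERCEPTION_INTENSITY_LEVELS): 1,
                        min(dz.PERCEPTION_INTENSITY_LEVELS): -1},
    "cue_mean_level_binary": {max(dz.PERCEPTION_MEANS): 1,
                              min(dz.PERCEPTION_MEANS): -1},
}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (x - np.mean(x)) / sd


def _code_binary(values: pd.Series, mapping: dict, name: str) -> np.ndarray:
    unknown = set(values.unique()) - set(mapping)
    if unknown:
        raise ValueError(f"unknown {name} labels: {sorted(map(str, unknown))}; "
                         f"expected {sorted(map(str, mapping))}")
    return values.map(mapping).to_numpy(dtype=float)


def build_design_matrix(trials: pd.DataFrame, scope: str = "all",
                        rating_col: str | None = None) -> pd.DataFrame:
    """Coded regressor matrix for external mixed-model tools.

    Binary factors (modality; cue SD level; and, in the cued-perception task,
    stimulus intensity and cue mean) are coded 1 (pain / high) vs -1 (vision /
    low); skewness enters as two dummies with the symmetric condition as
    reference; numeric covariates (cue mean in the expectation task, and the
    rating if ``rating_col`` is given) are z-scored over the table passed in
    (the z-scoring scope is recorded in the ``attrs``).
    """
    out = pd.DataFrame(index=trials.index)
    out["modality"] = _code_binary(trials["modality"], _BINARY_CODES["modality"],
                                   "modality")
    if "cue_sd_level" in trials and trials["cue_sd_level"].notna().all():
        out["cue_variance"] = _code_binary(trials["cue_sd_level"].astype(float),
                                           _BINARY_CODES["cue_sd_level"],
                                           "cue_sd_level")
    if "cue_mean_level" in trials and trials["cue_mean_level"].notna().all():
        means = trials["cue_mean_level"].astype(float)
        if set(means.unique()) <= set(dz.PERCEPTION_MEANS):
            out["cue_mean"] = _code_binary(means,
                                           _BINARY_CODES["cue_mean_level_binary"],
                                           "cue_mean_level")
        else:
            out["cue_mean"] = _zscore(means.to_numpy())
    if "intensity_level" in trials and trials["intensity_level"].notna().all():
        lvls = trials["intensity_level"].astype(float)
        if set(lvls.unique()) <= set(map(float, dz.PERCEPTION_INTENSITY_LEVELS)):
            out["intensity"] = _code_binary(lvls, _BINARY_CODES["intensity_level"],
                                            "intensity_level")
        else:
            out["intensity"] = _zscore(lvls.to_numpy())
    if "cue_skew_level" in trials and (trials["cue_skew_level"] != "").all():
        skew = trials["cue_skew_level"]
        unknown = set(skew.unique()) - set(dz.SKEW_LEVELS)
        if unknown:
            raise ValueError(f"unknown cue_skew_level labels: {sorted(unknown)}")
        out["skew_negative"] = (skew == "negative").astype(float)
        out["skew_positive"] = (skew == "positive").astype(float)
    if rating_col is not None:
        out["rating"] = _zscore(trials[rating_col].to_numpy(dtype=float))
    out.attrs["zscore_scope"] = scope
    return out


def decode_design_matrix(coded: pd.DataFrame) -> pd.DataFrame:
    """Invert the binary/dummy coding back to condition labels (round trip)."""
    out = pd.DataFrame(index=coded.index)
    out["modality"] = np.where(coded["modality"] > 0, "pain", "vision")
    if "cue_variance" in coded:
        out["cue_sd_level"] = np.where(coded["cue_variance"] > 0,
                                       max(dz.CUE_SDS), min(dz.CUE_SDS))
    if "skew_negative" in coded:
        out["cue_skew_level"] = np.select(
            [coded["skew_negative"] > 0, coded["skew_positive"] > 0],
            ["negative", "positive"], default="symmetric")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the requested stages in dependency order and write a manifest.

    ``config`` keys: ``seed`` (int, required), ``stages`` (subset of
    :data:`STAGES`, default all), ``cohort`` (CohortConfig field overrides).
    Outputs are CSV/JSON files under ``out_dir`` plus ``manifest.yaml`` with
    the package version, seed, config hash, and a checksum for every file.
    """
    stages = tuple(config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    seed = int(config["seed"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    def save_json(obj, name: str):
        path = out_dir / name
        path.write_text(json.dumps(obj, indent=2, default=float))
        written.append(path)

    cohort = None
    if "simulate" in stages:
        cfg = ch.CohortConfig(**config.get("cohort", {}))
        cohort = ch.simulate_cohort(cfg, rng)
        save_csv(cohort["truth_frame"], "truths.csv")
        save_csv(cohort["calibration_trials"], "calibration_trials.csv")
        save_csv(cohort["expectation_trials"], "expectation_trials.csv")
        save_csv(cohort["perception_trials"], "perception_trials.csv")

    exp_trials = per_trials = None
    if cohort is not None:
        exp_trials = cohort["expectation_trials"]
        per_trials = cohort["perception_trials"]

    if "exclude" in stages and exp_trials is not None:
        exp_trials, exp_log = ch.exclude_trials(exp_trials)
        per_trials, per_log = ch.exclude_trials(per_trials)
        save_csv(pd.concat([exp_log.assign(task="expectation"),
                            per_log.assign(task="cued_perception")],
                           ignore_index=True), "exclusions.csv")

    exp_fits = None
    if "fit_expectation" in stages and exp_trials is not None:
        exp_fits = ex.fit_expectation_table(exp_trials)
        save_csv(exp_fits, "expectation_fits.csv")

    if "group_tests" in stages and exp_fits is not None:
        save_json(ex.group_tests(exp_fits), "group_tests.json")

    fits_by_participant = None
    if "fit_perception" in stages and per_trials is not None and exp_fits is not None:
        per_trials = ch.attach_fitted_expectations(per_trials, exp_fits)
        fits_by_participant = {
            pid: pc.fit_all_models(grp, cohort["calibration_tables"][pid])
            for pid, grp in per_trials.groupby("participant_id")}
        save_csv(pc.fits_to_frame(fits_by_participant), "perception_fits.csv")

    if "compare" in stages and fits_by_participant is not None:
        save_json(pc.group_compare(fits_by_participant), "comparison.json")

    if "export" in stages and exp_trials is not None:
        save_csv(build_design_matrix(exp_trials, scope="expectation_task",
                                     rating_col="expectation_rating"),
                 "expectation_design_matrix.csv")
        save_csv(build_design_matrix(per_trials, scope="cued_perception_task",
                                     rating_col="perception_rating"),
                 "perception_design_matrix.csv")

    manifest = {
        "distcue_version": __version__,
        "seed": seed,
        "stages": list(stages),
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
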