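"""Factorial trial designs and constrained distributional-cue generation.

A *distribution cue* is a set of 10 ratings marked on a 0-100 visual analogue
scale (VAS), presented as the ratings of previous participants.  Cues are
characterised by the mean, standard deviation and skewness of their 10 values:
five means (expectation task) or two (cued-perception task), two SDs, and
three skew categories.  Symmetric cues are drawn from a normal law; skewed cues
take 9 draws from a moment-matched (shifted) log-normal law plus one injected
extreme element 2.0-2.5 realized SDs from the realized mean on the skew side.
Whole candidate sets are redrawn until the realized mean and SD are within
tolerance of their targets, every value lies on the scale, and the realized
skewness falls in its category band.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODALITIES = ("pain", "vision")
SKEW_LEVELS = ("negative", "symmetric", "positive")
CUE_SDS = (5.0, 12.5)
EXPECTATION_MEANS = (30.0, 40.0, 50.0, 60.0, 70.0)
PERCEPTION_MEANS = (30.0, 70.0)
#: stimulus intensity levels (1-5) used in the cued-perception task
PERCEPTION_INTENSITY_LEVELS = (2, 4)
SR_INTENSITY_LEVELS = (1, 2, 3, 4, 5)

N_CUE_VALUES = 10
SCALE_MIN, SCALE_MAX = 0.0, 100.0

#: realized-skewness category bounds
SYMMETRIC_SKEW_BOUND = 0.035
SKEWED_SKEW_BOUND = 0.3
#: injected extreme element sits this many realized SDs from the realized mean
EXTREME_SD_LO, EXTREME_SD_HI = 2.0, 2.5
#: |realized - target| tolerance for cue mean and SD, VAS units
MOMENT_TOL = 1.0

#: log-scale shape of the skewed sampling law (skewness ~ 1.75 before the
#: extreme element); the shifted log-normal decouples shape from mean/SD
_LOGNORMAL_SIGMA = 0.5

TASKS = ("stimulus_response", "expectation", "cued_perception")


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson standardized third moment (G1).

    Raises ``ValueError`` for fewer than three values or zero variance.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("skewness requires at least 3 values")
    if np.var(v) == 0.0:
        raise ValueError("skewness undefined for zero-variance data")
    return float(stats.skew(v, bias=False))


@dataclass(frozen=True)
class CueSpec:
    """Design cell of one cue: modality, target mean/SD, skew category."""

    modality: str
    mean_target: float
    sd_target: float
    skew_level: str

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.skew_level not in SKEW_LEVELS:
            raise ValueError(f"skew_level must be one of {SKEW_LEVELS}")
        allowed = set(EXPECTATION_MEANS) | set(PERCEPTION_MEANS)
        if float(self.mean_target) not in allowed:
            raise ValueError(f"mean_target must be in {sorted(allowed)}")
        if float(self.sd_target) not in CUE_SDS:
            raise ValueError(f"sd_target must be in {CUE_SDS}")


@dataclass
class Cue:
    """One realized 10-value cue distribution with its design cell.

    ``extreme_index`` marks the injected extreme element of skewed cues
    (``None`` for symmetric cues).
    """

    values: np.ndarray
    spec: CueSpec
    extreme_index: int | None = None
    realized_mean: float = field(init=False)
    realized_sd: float = field(init=False)
    realized_skew: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CUE_VALUES,):
            raise ValueError(f"a cue holds exactly {N_CUE_VALUES} values")
        self.realized_mean = float(np.mean(self.values))
        self.realized_sd = float(np.std(self.values, ddof=1))
        self.realized_skew = sample_skewness(self.values)

    def validate(self) -> None:
        """Raise ``ValueError`` if any cue invariant is violated."""
        v = self.values
        if np.any(v < SCALE_MIN) or np.any(v > SCALE_MAX):
            raise ValueError("cue values outside the 0-100 VAS")
        lvl = self.spec.skew_level
        g1 = self.realized_skew
        if lvl == "symmetric":
            if abs(g1) > SYMMETRIC_SKEW_BOUND:
                raise ValueError(f"|skew|={abs(g1):.4f} exceeds symmetric band")
        elif lvl == "positive":
            if g1 <= SKEWED_SKEW_BOUND:
                raise ValueError(f"skew={g1:.4f} not > {SKEWED_SKEW_BOUND}")
        else:
            if g1 >= -SKEWED_SKEW_BOUND:
                raise ValueError(f"skew={g1:.4f} not < -{SKEWED_SKEW_BOUND}")
        if lvl != "symmetric":
            if self.extreme_index is None:
                raise ValueError("skewed cue lacks a designated extreme element")
            d = self.extreme_distance()
            if not (EXTREME_SD_LO - 1e-9 <= d <= EXTREME_SD_HI + 1e-9):
                raise ValueError(f"extreme element at {d:.3f} SD, outside 2.0-2.5")
            dev = v[self.extreme_index] - self.realized_mean
            if (lvl == "positive") != (dev > 0):
                raise ValueError("extreme element on the wrong side of the mean")

    def extreme_distance(self) -> float:
        """Standardized distance of the designated extreme element, in SDs."""
        if self.extreme_index is None:
            raise ValueError("cue has no designated extreme element")
        return abs(self.values[self.extreme_index] - self.realized_mean) / self.realized_sd


def _g1_rows(v: np.ndarray) -> np.ndarray:
    """Row-wise adjusted Fisher-Pearson G1 for a 2-D candidate batch."""
    n = v.shape[1]
    dev = v - v.mean(axis=1, keepdims=True)
    m2 = np.mean(dev**2, axis=1)
    m3 = np.mean(dev**3, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g1 = m3 / m2**1.5
    return g1 * np.sqrt(n * (n - 1)) / (n - 2)


def _accept_common(v: np.ndarray, spec: CueSpec) -> tuple[np.ndarray, np.ndarray]:
    """Range + moment-tolerance acceptance mask and row G1 for a batch."""
    ok = np.all((v >= SCALE_MIN) & (v <= SCALE_MAX), axis=1)
    ok &= np.abs(v.mean(axis=1) - spec.mean_target) <= MOMENT_TOL
    ok &= np.abs(v.std(axis=1, ddof=1) - spec.sd_target) <= MOMENT_TOL
    g1 = _g1_rows(v)
    return ok, g1


def _symmetric_batch(spec: CueSpec, rng: np.random.Generator, size: int) -> np.ndarray | None:
    v = rng.normal(spec.mean_target, spec.sd_target, size=(size, N_CUE_VALUES))
    ok, g1 = _accept_common(v, spec)
    ok &= np.abs(g1) <= SYMMETRIC_SKEW_BOUND
    idx = np.flatnonzero(ok)
    return v[idx[0]] if idx.size else None


def _solve_extreme(s: np.ndarray, q: np.ndarray, d: np.ndarray, positive: bool) -> np.ndarray:
    """Value x such that appending x to 9 values (sum s, sum-of-squares q)
    puts x exactly d sample SDs from the 10-value mean, on the given side.

    From (9x - s)/10 = +/- d * sd10 one obtains the quadratic
    (729 - 90 d^2) x^2 + s (20 d^2 - 162) x + 9 s^2 - 10 d^2 (10 q - s^2) = 0;
    the root above (below) the 9-value mean gives the positive (negative) case.
    """
    a = 729.0 - 90.0 * d**2
    b = s * (20.0 * d**2 - 162.0)
    c = 9.0 * s**2 - 10.0 * d**2 * (10.0 * q - s**2)
    disc = b**2 - 4.0 * a * c
    disc = np.where(disc < 0, np.nan, disc)
    root = np.sqrt(disc)
    return (-b + root) / (2.0 * a) if positive else (-b - root) / (2.0 * a)


def _skewed_batch(
    spec: CueSpec, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, int] | None:
    positive = spec.skew_level == "positive"
    M, S = spec.mean_target, spec.sd_target
    d = rng.uniform(EXTREME_SD_LO, EXTREME_SD_HI, size=size)
    # pre-compensate the 9-draw moments so the 10-value set lands near (M, S):
    # if the final set had mean M, SD S and the extreme exactly d SDs out, the
    # other nine would have mean M -/+ dS/9 and variance S^2 (81 - 10 d^2)/72
    sign = 1.0 if positive else -1.0
    m9 = M - sign * d * S / 9.0
    sd9 = S * np.sqrt((81.0 - 10.0 * d**2) / 72.0)
    sig = _LOGNORMAL_SIGMA
    scale = sd9 / np.sqrt(np.expm1(sig**2))  # E[exp term] of the shifted law
    mu = np.log(scale) - sig**2 / 2.0
    y = rng.lognormal(mean=0.0, sigma=sig, size=(size, 9)) * np.exp(mu)[:, None]
    origin = m9 - scale
    v9 = origin[:, None] + y
    if not positive:
        v9 = 2.0 * m9[:, None] - v9  # mirror about the 9-draw target mean
    s = v9.sum(axis=1)
    q = (v9**2).sum(axis=1)
    with np.errstate(invalid="ignore"):
        x = _solve_extreme(s, q, d, positive)
    v = np.concatenate([v9, x[:, None]], axis=1)
    valid = np.isfinite(x)
    v_chk = np.where(valid[:, None], v, 0.0)
    ok, g1 = _accept_common(v_chk, spec)
    ok &= valid
    ok &= (g1 > SKEWED_SKEW_BOUND) if positive else (g1 < -SKEWED_SKEW_BOUND)
    idx = np.flatnonzero(ok)
    if not idx.size:
        return None
    chosen = v[idx[0]]
    # shuffle presentation order of the 10 marks, tracking the extreme element
    perm = rng.permutation(N_CUE_VALUES)
    return chosen[perm], int(np.flatnonzero(perm == 9)[0])


def generate_cue(
    spec: CueSpec,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 10_000,
    _batch: int = 256,
) -> Cue:
    """Generate one constrained cue distribution by batched rejection sampling.

    Candidate 10-value sets are redrawn until every value lies in [0, 100],
    the realized mean and SD are within 1 VAS unit of target, and the realized
    skewness falls in its category band; skewed cues additionally carry one
    injected extreme element exactly 2.0-2.5 realized SDs from the realized
    mean (the window position is drawn uniformly).
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    if spec.sd_target <= 0:
        raise ValueError("sd_target must be positive")
    rng = np.random.default_rng(rng)
    attempts = 0
    while attempts < max_attempts:
        size = min(_batch, max_attempts - attempts)
        attempts += size
        if spec.skew_level == "symmetric":
            hit = _symmetric_batch(spec, rng, size)
            if hit is not None:
                cue = Cue(values=hit, spec=spec, extreme_index=None)
                cue.validate()
                return cue
        else:
            out = _skewed_batch(spec, rng, size)
            if out is not None:
                cue = Cue(values=out[0], spec=spec, extreme_index=out[1])
                cue.validate()
                return cue
    raise RuntimeError(
        f"no admissible cue for {spec} within {max_attempts} attempts "
        "(mean/SD tolerance, scale range, or skew-category constraint unmet)"
    )


# ---------------------------------------------------------------------------
# design enumeration


def _check_task(task: str) -> None:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; valid tasks are {TASKS}")


def enumerate_design(
    task: str,
    rng: np.random.Generator | int | None = None,
    modality_order: str = "pain_first",
) -> pd.DataFrame:
    """Full factorial trial list of one task, trial order randomized within block.

    Expectation task: 2 modalities x 5 cue means x 2 SDs x 3 skew levels = 60
    cells, 6 repetitions (360 trials) in six single-modality blocks of 60.
    Cued-perception task: 2 modalities x 2 intensities x 2 cue means x 2 SDs x
    3 skew levels = 48 cells, 3 repetitions (144 trials) in six blocks of 24,
    each split into two single-modality 12-trial mini-blocks.
    Stimulus-response task: 2 modalities x 5 intensities x 5 repetitions = 50
    trials in two single-modality blocks of 25.
    """
    _check_task(task)
    if modality_order not in ("pain_first", "vision_first"):
        raise ValueError("modality_order must be 'pain_first' or 'vision_first'")
    rng = np.random.default_rng(rng)
    first, second = (
        ("pain", "vision") if modality_order == "pain_first" else ("vision", "pain")
    )
    rows: list[dict] = []

    if task == "stimulus_response":
        for block, mod in enumerate((first, second), start=1):
            cells = [
                {"modality": mod, "intensity_level": lvl}
                for lvl in SR_INTENSITY_LEVELS
                for _ in range(5)
            ]
            rng.shuffle(cells)
            for i, cell in enumerate(cells, start=1):
                rows.append({"task": task, "block": block, "mini_block": 1,
                             "trial": i, **cell,
                             "cue_mean_level": np.nan, "cue_sd_level": np.nan,
                             "cue_skew_level": ""})

    elif task == "expectation":
        base = list(itertools.product(EXPECTATION_MEANS, CUE_SDS, SKEW_LEVELS))
        for block in range(1, 7):
            mod = first if block <= 3 else second
            cells = [
                {"modality": mod, "cue_mean_level": m, "cue_sd_level": sd,
                 "cue_skew_level": sk}
                for (m, sd, sk) in base
                for _ in range(2)  # 2 per block x 3 same-modality blocks = 6 reps
            ]
            rng.shuffle(cells)
            for i, cell in enumerate(cells, start=1):
                rows.append({"task": task, "block": block, "mini_block": 1,
                             "trial": i, "intensity_level": np.nan, **cell})

    else:  # cued_perception
        base = list(itertools.product(
            PERCEPTION_INTENSITY_LEVELS, PERCEPTION_MEANS, CUE_SDS, SKEW_LEVELS))
        per_mod: dict[str, list[dict]] = {}
        for mod in (first, second):
            cells = [
                {"modality": mod, "intensity_level": lvl, "cue_mean_level": m,
                 "cue_sd_level": sd, "cue_skew_level": sk}
                for (lvl, m, sd, sk) in base
                for _ in range(3)
            ]
            rng.shuffle(cells)
            per_mod[mod] = cells  # 72 trials -> six mini-blocks of 12
        for block in range(1, 7):
            mb_order = [first, second] if rng.random() < 0.5 else [second, first]
            trial = 0
            for mb, mod in enumerate(mb_order, start=1):
                chunk = per_mod[mod][(block - 1) * 12 : block * 12]
                for cell in chunk:
                    trial += 1
                    rows.append({"task": task, "block": block, "mini_block": mb,
                                 "trial": trial, **cell})

    df = pd.DataFrame(rows)
    return df[["task", "block", "mini_block", "trial", "modality",
               "intensity_level", "cue_mean_level", "cue_sd_level",
               "cue_skew_level"]]


def cue_columns() -> list[str]:
    return [f"cue_v{i}" for i in range(1, N_CUE_VALUES + 1)]


def generate_cues_for_design(
    design: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 10_000,
) -> pd.DataFrame:
    """Attach a freshly generated cue (cue_v1..cue_v10) to every design row."""
    rng = np.random.default_rng(rng)
    out = design.copy()
    vals = np.full((len(design), N_CUE_VALUES), np.nan)
    extreme = np.full(len(design), -1, dtype=int)
    for j, (_, row) in enumerate(design.iterrows()):
        if not isinstance(row["cue_skew_level"], str) or not row["cue_skew_level"]:
            continue
        spec = CueSpec(
            modality=row["modality"],
            mean_target=float(row["cue_mean_level"]),
            sd_target=float(row["cue_sd_level"]),
            skew_level=row["cue_skew_level"],
        )
        cue = generate_cue(spec, rng, max_attempts=max_attempts)
        vals[j] = cue.values
        extreme[j] = -1 if cue.extreme_index is None else cue.extreme_index
    out[cue_columns()] = vals
    out["cue_extreme_index"] = extreme
    return out


def cues_from_frame(df: pd.DataFrame) -> np.ndarray:
    """(n_trials, 10) cue-value matrix from a trial table."""
    return df[cue_columns()].to_numpy(dtype=float)
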