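"""Synthetic stroke-patient cohorts for exercising the whole pipeline.

No individual-level data are distributed with this package, so every stage
is tested against simulated cohorts whose *marginal* covariate
distributions match the published cohort summary (age 64.53 ± 7.87 y, BMI
24.85 ± 3.44 kg/m², spot Na 131.85 ± 62.88 mmol/L, spot K 55.79 ±
36.09 mmol/L, spot Cr 8.93 ± 5.60 mmol/L, 24 h volume 1.60 ± 0.60 L,
54.7 % male) and whose measured 24 h excretions follow the published
sex-specific linear predictors plus Gaussian residual noise.  The residual
SD of each model is either given directly or calibrated so that refitting
the model attains a target multiple correlation R (0.42 male / 0.33 female
for sodium, 0.71 for potassium), via

    sigma = sd(linear predictor) * sqrt(1/R**2 - 1).

Covariates are drawn independently (truncated normals; spot creatinine is
moment-matched log-normal, since mean 8.93 / SD 5.60 with positivity
implies right skew); heights are invented plumbing for the anthropometric
creatinine sub-models and are not fidelity targets.  Because covariates are
independent, downstream agreement statistics on synthetic cohorts are *not*
expected to match any published validation table.

Optional contamination injects QC-rule violations at configurable per-rule
rates so that the exclusion filters can be tested against known counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import estimators as est
from .estimators import Sex, COHORT_COLUMNS

__all__ = ["SyntheticParams", "SyntheticCohort", "calibrate_sigma",
           "generate_cohort", "make_fixture"]

#: contamination keys, matching the QC reason codes
CONTAMINATION_RULES = ["missed_fraction", "volume_low", "cr24_out_of_range",
                       "volume_3sd", "spotcr_3sd"]


@dataclass(frozen=True)
class SyntheticParams:
    """Generator configuration.

    Marginals are (mean, sd, lower, upper) truncated-normal tuples except
    spot creatinine, which is log-normal moment-matched to (mean, sd).
    ``target_r`` holds the multiple-correlation targets used to calibrate
    residual noise; ``sigma_na``/``sigma_k`` override calibration with a
    fixed residual SD (mmol/day).  ``outcome_floor_na``/``_k`` optionally
    rejection-resample outcomes below a floor; they default to ``None``
    because any binding floor distorts the linear data-generating model.
    ``contamination`` maps QC rule names to per-record violation
    probabilities (rates must sum to at most 1).
    """

    n: int = 970
    male_fraction: float = 0.547
    age: tuple = (64.53, 7.87, 40.0, 90.0)          # years
    bmi: tuple = (24.85, 3.44, 15.0, 45.0)          # kg/m^2
    spot_na: tuple = (131.85, 62.88, 5.0, np.inf)   # mmol/L
    spot_k: tuple = (55.79, 36.09, 2.0, np.inf)     # mmol/L
    spot_cr_mean: float = 8.93                      # mmol/L (log-normal)
    spot_cr_sd: float = 5.60
    day_volume: tuple = (1.60, 0.60, 0.5, np.inf)   # L; floor = QC minimum
    height_male: tuple = (165.0, 8.0)               # cm (invented, non-fidelity)
    height_female: tuple = (155.0, 7.0)
    u24_cr_male: tuple = (9.3, 2.2, 6.0, 30.0)      # mmol/day, inside QC band
    u24_cr_female: tuple = (6.6, 1.6, 4.0, 25.0)
    target_r: dict = field(default_factory=lambda: {
        "na_male": 0.42, "na_female": 0.33, "k": 0.71})
    sigma_na: float | None = None                   # mmol/day; None = calibrate
    sigma_k: float | None = None
    outcome_floor_na: float | None = None           # mmol/day; None = no floor
    outcome_floor_k: float | None = None
    contamination: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must lie in [0, 1]")
        for key, r in self.target_r.items():
            if not 0 < r < 1:
                raise ValueError(f"target_r[{key!r}] must lie strictly in (0, 1)")
        bad = [k for k in self.contamination if k not in CONTAMINATION_RULES]
        if bad:
            raise ValueError(f"unknown contamination rules: {bad}")
        if sum(self.contamination.values()) > 1:
            raise ValueError("contamination rates must sum to at most 1")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its provenance."""

    records: pd.DataFrame
    params: SyntheticParams
    seed: int
    residual_sd: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        p = asdict(self.params)
        p["spot_na"] = list(np.asarray(p["spot_na"], float))
        p["spot_k"] = list(np.asarray(p["spot_k"], float))
        p["day_volume"] = list(np.asarray(p["day_volume"], float))
        return {"seed": self.seed, "residual_sd": self.residual_sd,
                "params": json.loads(json.dumps(p, default=float))}

    def write(self, csv_path, sidecar_path=None) -> None:
        est.write_cohort(self.records, csv_path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.provenance(), fh, indent=2)


def calibrate_sigma(lin_pred_sd: float, target_r: float) -> float:
    """Residual SD giving multiple correlation ``target_r``.

    From R² = Var(lin)/(Var(lin) + σ²):  σ = sd(lin) · sqrt(1/R² − 1).
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must lie strictly in (0, 1)")
    if lin_pred_sd <= 0:
        raise ValueError("lin_pred_sd must be positive")
    return float(lin_pred_sd * np.sqrt(1.0 / target_r ** 2 - 1.0))


@lru_cache(maxsize=64)
def _truncnorm_underlying(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) whose truncation to [lo, hi] has the target
    mean and SD.  Without this, a binding bound (e.g. spot K > 2 with a
    wide nominal SD) would shift the realized mean well off the target."""
    def gap(x):
        mu, lsig = x
        sig = float(np.exp(lsig))
        a = (lo - mu) / sig
        b = (hi - mu) / sig if np.isfinite(hi) else np.inf
        d = stats.truncnorm(a, b, loc=mu, scale=sig)
        return [float(d.mean()) - mean, float(d.std()) - sd]
    sol = optimize.fsolve(gap, [mean, np.log(sd)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def _truncnorm(rng, mean, sd, lo, hi, size):
    mu, sig = _truncnorm_underlying(float(mean), float(sd), float(lo),
                                    float(hi))
    a = (lo - mu) / sig
    b = (hi - mu) / sig if np.isfinite(hi) else np.inf
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=size,
                               random_state=rng)


def _floored_noise(rng, lin, sigma, floor):
    """Gaussian noise around ``lin``; resample below ``floor`` if set."""
    y = lin + rng.normal(0.0, sigma, len(lin))
    if floor is None:
        return y
    bad = y <= floor
    tries = 0
    while bad.any() and tries < 1000:
        y[bad] = lin[bad] + rng.normal(0.0, sigma, bad.sum())
        bad = y <= floor
        tries += 1
    return np.maximum(y, floor)


def generate_cohort(params: SyntheticParams | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Draw a full cohort; reproducible from ``(params, seed)``.

    ``seed`` overrides ``params.seed`` when given.  Covariates and spot
    concentrations come from the configured marginals; weight is derived
    as BMI · (height/100)²; measured 24 h Na and K are the sex-specific
    linear predictors of the new formulas plus Gaussian noise with a
    per-model residual SD (fixed or calibrated to the target multiple
    correlations); 24 h creatinine is truncated normal inside the QC
    plausibility bands; missed volume is zero except on contaminated
    records.
    """
    params = params or SyntheticParams()
    if seed is not None:
        params = replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)
    n = params.n

    male = rng.random(n) < params.male_fraction
    age = _truncnorm(rng, *params.age, n)
    bmi = _truncnorm(rng, *params.bmi, n)
    spot_na = _truncnorm(rng, *params.spot_na, n)
    spot_k = _truncnorm(rng, *params.spot_k, n)
    # moment-matched log-normal spot creatinine
    cv2 = (params.spot_cr_sd / params.spot_cr_mean) ** 2
    slog = np.sqrt(np.log1p(cv2))
    mlog = np.log(params.spot_cr_mean) - slog ** 2 / 2
    spot_cr = rng.lognormal(mlog, slog, n)
    vol = _truncnorm(rng, *params.day_volume, n)

    height = np.where(male,
                      rng.normal(*params.height_male, n),
                      rng.normal(*params.height_female, n))
    weight = bmi * (height / 100.0) ** 2

    u24_cr = np.empty(n)
    u24_cr[male] = _truncnorm(rng, *params.u24_cr_male, int(male.sum()))
    u24_cr[~male] = _truncnorm(rng, *params.u24_cr_female, int((~male).sum()))

    # measured outcomes from the published linear predictors + noise
    lin_na = np.empty(n)
    lin_k = np.empty(n)
    for sex, mask in ((Sex.MALE, male), (Sex.FEMALE, ~male)):
        if mask.any():
            lin_na[mask] = est.estimate_na_new(
                sex, age[mask], bmi[mask],
                spot_na=spot_na[mask], spot_cr=spot_cr[mask])
            lin_k[mask] = est.estimate_k_new(
                sex, age[mask], bmi[mask], spot_k=spot_k[mask],
                spot_na=spot_na[mask], spot_cr=spot_cr[mask])

    residual_sd: dict[str, float] = {}
    u24_na = np.empty(n)
    for sex_key, mask in (("na_male", male), ("na_female", ~male)):
        if not mask.any():
            continue
        if params.sigma_na is not None:
            sig = float(params.sigma_na)
        else:
            sig = calibrate_sigma(float(lin_na[mask].std(ddof=1)),
                                  params.target_r[sex_key])
        residual_sd[sex_key] = sig
        u24_na[mask] = _floored_noise(rng, lin_na[mask], sig,
                                      params.outcome_floor_na)
    u24_k = np.empty(n)
    for sex_key, mask in (("k_male", male), ("k_female", ~male)):
        if not mask.any():
            continue
        if params.sigma_k is not None:
            sig = float(params.sigma_k)
        else:
            sig = calibrate_sigma(float(lin_k[mask].std(ddof=1)),
                                  params.target_r["k"])
        residual_sd[sex_key] = sig
        u24_k[mask] = _floored_noise(rng, lin_k[mask], sig,
                                     params.outcome_floor_k)

    missed = np.zeros(n)
    df = pd.DataFrame({
        "id": [f"S{i:05d}" for i in range(n)],
        "sex": np.where(male, "M", "F"),
        "age_y": age, "height_cm": height, "weight_kg": weight, "bmi": bmi,
        "spot_na_mmol_l": spot_na, "spot_k_mmol_l": spot_k,
        "spot_cr_mmol_l": spot_cr,
        "u24_vol_l": vol, "u24_na_mmol": u24_na, "u24_k_mmol": u24_k,
        "u24_cr_mmol": u24_cr, "missed_l": missed,
    })

    if params.contamination:
        _contaminate(df, params, rng)
    return SyntheticCohort(records=df, params=params, seed=params.seed,
                           residual_sd=residual_sd)


def _contaminate(df: pd.DataFrame, params: SyntheticParams, rng) -> None:
    """Inject QC violations in place; each record trips at most one rule."""
    n = len(df)
    rules = [r for r in CONTAMINATION_RULES if params.contamination.get(r, 0) > 0]
    probs = [params.contamination[r] for r in rules]
    draw = rng.choice(len(rules) + 1, size=n,
                      p=list(probs) + [1 - sum(probs)])
    for j, rule in enumerate(rules):
        idx = np.flatnonzero(draw == j)
        if idx.size == 0:
            continue
        if rule == "missed_fraction":
            # missed fraction of the total in (0.25, 0.40) — safely over 0.20
            f = rng.uniform(0.25, 0.40, idx.size)
            df.loc[df.index[idx], "missed_l"] = (
                f / (1 - f) * df["u24_vol_l"].to_numpy()[idx])
        elif rule == "volume_low":
            df.loc[df.index[idx], "u24_vol_l"] = rng.uniform(0.10, 0.45, idx.size)
        elif rule == "cr24_out_of_range":
            male = df["sex"].to_numpy()[idx] == "M"
            lo = np.where(male, params.u24_cr_male[2], params.u24_cr_female[2])
            df.loc[df.index[idx], "u24_cr_mmol"] = lo * rng.uniform(0.3, 0.9, idx.size)
        elif rule == "volume_3sd":
            m, s = params.day_volume[0], params.day_volume[1]
            df.loc[df.index[idx], "u24_vol_l"] = m + rng.uniform(4.0, 6.0, idx.size) * s
        elif rule == "spotcr_3sd":
            m, s = params.spot_cr_mean, params.spot_cr_sd
            df.loc[df.index[idx], "spot_cr_mmol_l"] = m + rng.uniform(4.0, 6.0, idx.size) * s


# --------------------------------------------------------------------------
# hand-checkable fixtures
# --------------------------------------------------------------------------

def _base_record(i, sex, age, bmi, na, k, cr, vol=1.5, u24cr=None):
    height = 165.0 if sex == "M" else 155.0
    weight = bmi * (height / 100.0) ** 2
    if u24cr is None:
        u24cr = 9.0 if sex == "M" else 7.0
    return {
        "id": f"F{i:03d}", "sex": sex, "age_y": age, "height_cm": height,
        "weight_kg": weight, "bmi": bmi, "spot_na_mmol_l": na,
        "spot_k_mmol_l": k, "spot_cr_mmol_l": cr, "u24_vol_l": vol,
        "u24_na_mmol": 180.0, "u24_k_mmol": 45.0, "u24_cr_mmol": u24cr,
        "missed_l": 0.0,
    }


def make_fixture(name: str) -> pd.DataFrame:
    """Small deterministic cohorts for hand-checking.

    ``tiny``
        12 round-number records, both sexes.
    ``qc_violations``
        12 clean records plus exactly one violator per QC rule (5 total).
    ``perfect_agreement``
        the tiny cohort with measured 24 h Na/K set exactly to the new
        formula's estimate, so every agreement metric sits at its ideal.
    """
    if name == "tiny":
        rows = []
        specs = [("M", 55, 22, 100, 40, 8), ("M", 60, 24, 120, 50, 9),
                 ("M", 65, 25, 130, 55, 9), ("M", 70, 26, 150, 60, 10),
                 ("M", 62, 23, 140, 45, 7), ("M", 58, 27, 110, 65, 11),
                 ("F", 56, 21, 90, 35, 6), ("F", 61, 24, 105, 48, 7),
                 ("F", 66, 25, 125, 52, 8), ("F", 71, 26, 145, 58, 9),
                 ("F", 63, 23, 135, 42, 6), ("F", 59, 28, 115, 62, 10)]
        for i, (sex, age, bmi, na, k, cr) in enumerate(specs):
            rows.append(_base_record(i, sex, age, bmi, na, k, cr,
                                     vol=1.2 + 0.1 * (i % 5)))
        return pd.DataFrame(rows)
    if name == "qc_violations":
        df = make_fixture("tiny")
        bad = [
            # rule 1: missed 0.5 L of a 1.5 L collection -> fraction 0.25
            dict(_base_record(100, "M", 60, 24, 120, 50, 9), missed_l=0.5),
            # rule 2: 0.4 L collected
            dict(_base_record(101, "F", 60, 24, 120, 50, 9), u24_vol_l=0.4),
            # rule 3: woman with 24 h creatinine 3.5 mmol/day
            dict(_base_record(102, "F", 60, 24, 120, 50, 9), u24_cr_mmol=3.5),
            # rule 4: 24 h volume far above the clean spread
            dict(_base_record(103, "M", 60, 24, 120, 50, 9), u24_vol_l=9.0),
            # rule 5: spot creatinine far above the clean spread
            dict(_base_record(104, "M", 60, 24, 120, 50, 40.0)),
        ]
        return pd.concat([df, pd.DataFrame(bad)], ignore_index=True)
    if name == "perfect_agreement":
        df = make_fixture("tiny")
        for sex_label, sex in (("M", Sex.MALE), ("F", Sex.FEMALE)):
            m = (df["sex"] == sex_label).to_numpy()
            df.loc[m, "u24_na_mmol"] = est.estimate_na_new(
                sex, df["age_y"][m], df["bmi"][m],
                spot_na=df["spot_na_mmol_l"][m], spot_cr=df["spot_cr_mmol_l"][m])
            df.loc[m, "u24_k_mmol"] = est.estimate_k_new(
                sex, df["age_y"][m], df["bmi"][m], spot_k=df["spot_k_mmol_l"][m],
                spot_na=df["spot_na_mmol_l"][m], spot_cr=df["spot_cr_mmol_l"][m])
        return df
    raise ValueError(f"unknown fixture {name!r}")
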