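"""Spot-urine estimating equations for 24 h urinary sodium and potassium excretion.

A single casual ("spot") urine specimen is far cheaper to collect than a full
24 h collection, so estimating equations that map spot concentrations plus
demographics onto 24 h excretion are widely used in population salt-intake
surveillance.  This module evaluates four such equations:

* the **new** sex-specific linear formulas developed for Chinese stroke
  patients (terms: age, BMI, spot Na, spot Na/Cr for sodium; age, BMI,
  spot K, ln(K/Cr), ln(Na/Cr) for potassium);
* the **Kawasaki** equations (second-morning urine, Japanese adults), which
  scale the analyte-to-creatinine ratio by a predicted 24 h creatinine
  excretion and take a square root;
* the **INTERSALT** sodium equations (casual urine, multinational), plain
  linear forms with a female age-squared term; and
* the **Tanaka** equations (casual urine, Japanese adults), a power-law
  analogue of Kawasaki with a single sex-free creatinine sub-model.

All formulas take spot concentrations in mmol/L and return mmol/day.  The
Kawasaki and Tanaka forms internally convert spot creatinine to mg/L
(creatinine molar mass 113.12 g/mol); the INTERSALT and new formulas use
mmol/L throughout, including in the Na/Cr ratio.

Every printed coefficient lives in the table-driven :data:`COEFFICIENTS`
registry so that transcription can be audited in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "EstimatorId",
    "ParticipantRecord",
    "SpotSpecimen",
    "DayUrine",
    "EstimateResult",
    "COEFFICIENTS",
    "CREATININE_MG_PER_MMOL",
    "NACL_G_PER_MMOL_NA",
    "cr_mmol_to_mg",
    "na_mmol_to_g_salt",
    "estimate_na_new",
    "estimate_k_new",
    "predict_creatinine_kawasaki",
    "predict_creatinine_tanaka",
    "estimate_kawasaki",
    "estimate_tanaka",
    "estimate_na_intersalt",
    "estimate_all",
    "estimate_batch",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

# --------------------------------------------------------------------------
# constants and enumerations
# --------------------------------------------------------------------------

#: mg of creatinine per mmol (molar mass 113.12 g/mol).
CREATININE_MG_PER_MMOL = 113.12

#: g of NaCl per mmol of sodium (molar mass of NaCl 58.44 g/mol).
NACL_G_PER_MMOL_NA = 0.05844


class Sex(Enum):
    """Biological sex; every sex-specific equation dispatches on it."""

    MALE = "M"
    FEMALE = "F"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().upper()
        if v in ("M", "MALE"):
            return cls.MALE
        if v in ("F", "FEMALE"):
            return cls.FEMALE
        raise ValueError(f"cannot parse sex from {value!r}")


class EstimatorId(Enum):
    """Identifier of an estimating equation.

    INTERSALT supports sodium only; no INTERSALT potassium equation exists.
    """

    NEW = "new"
    KAWASAKI = "kawasaki"
    INTERSALT = "intersalt"
    TANAKA = "tanaka"


# --------------------------------------------------------------------------
# coefficient registry (single source of truth for all printed coefficients)
# --------------------------------------------------------------------------

COEFFICIENTS: dict = {
    "new": {
        "na": {
            # est 24UNaV (mmol/day) = b0 + b_age*age + b_bmi*bmi
            #                          + b_na*spot_na + b_ratio*(spot_na/spot_cr)
            Sex.MALE: {
                "intercept": 41.492,
                "age": -0.191,
                "bmi": 4.349,
                "spot_na": 0.229,
                "na_cr_ratio": 1.744,
            },
            Sex.FEMALE: {
                "intercept": 147.159,
                "age": -1.030,
                "bmi": 2.011,
                "spot_na": 0.143,
                "na_cr_ratio": 1.035,
            },
        },
        "k": {
            # est 24UKV (mmol/day) = b0 + b_age*age + b_bmi*bmi + b_k*spot_k
            #                         + b_lnkcr*ln(k/cr) + b_lnnacr*ln(na/cr)
            Sex.MALE: {
                "intercept": -1.035,
                "age": -0.052,
                "bmi": 0.410,
                "spot_k": 0.031,
                "ln_k_cr": 33.280,
                "ln_na_cr": -5.789,
            },
            Sex.FEMALE: {
                "intercept": 4.318,
                "age": -0.235,
                "bmi": 0.530,
                "spot_k": 0.040,
                "ln_k_cr": 30.990,
                "ln_na_cr": -7.837,
            },
        },
    },
    "kawasaki": {
        # PrUCr24h (mg/day) = b_w*weight + b_h*height + b_age*age + b0
        "prucr": {
            Sex.MALE: {"weight": 15.12, "height": 7.39, "age": -12.63, "intercept": -79.90},
            Sex.FEMALE: {"weight": 8.58, "height": 5.09, "age": -4.72, "intercept": -74.50},
        },
        # est = const * (analyte mmol/L / cr mg/L * PrUCr24h) ** exponent
        "na": {"const": 16.30, "exponent": 0.5},
        "k": {"const": 7.20, "exponent": 0.5},
    },
    "tanaka": {
        "prucr": {"weight": 14.89, "height": 16.14, "age": -2.04, "intercept": -2244.45},
        "na": {"const": 21.98, "exponent": 0.392},
        "k": {"const": 7.59, "exponent": 0.431},
    },
    "intersalt": {
        # spot cr stays in mmol/L here (no unit conversion)
        "na": {
            Sex.MALE: {
                "intercept": 25.46,
                "spot_na": 0.46,
                "spot_cr": -2.75,
                "spot_k": -0.13,
                "bmi": 4.10,
                "age": 0.26,
                "age2": 0.0,
            },
            Sex.FEMALE: {
                "intercept": 5.07,
                "spot_na": 0.34,
                "spot_cr": -2.16,
                "spot_k": -0.09,
                "bmi": 2.39,
                "age": 2.35,
                "age2": -0.03,
            },
        },
    },
}


# --------------------------------------------------------------------------
# domain records
# --------------------------------------------------------------------------

#: maximum tolerated gap between a reported BMI and weight/(height/100)^2
BMI_CONSISTENCY_TOL = 0.5


@dataclass(frozen=True)
class SpotSpecimen:
    """Spot-urine concentrations, all in mmol/L.

    Creatinine must be strictly positive: it is a divisor in every formula.
    """

    na: float
    k: float
    cr: float

    def __post_init__(self):
        if self.na < 0 or self.k < 0:
            raise ValueError("spot na and k must be non-negative")
        if self.cr <= 0:
            raise ValueError("spot creatinine must be strictly positive")


@dataclass(frozen=True)
class DayUrine:
    """One participant's 24 h urine collection.

    volume in L/day; na, k, cr in mmol/day; missed_volume is the
    self-reported urine volume (L) not captured in the containers.
    """

    volume: float
    na: float
    k: float
    cr: float
    missed_volume: float = 0.0

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("24 h urine volume must be positive")
        if min(self.na, self.k, self.cr) < 0:
            raise ValueError("24 h totals must be non-negative")
        if self.missed_volume < 0:
            raise ValueError("missed volume must be non-negative")


@dataclass(frozen=True)
class ParticipantRecord:
    """Demographics and anthropometrics of one subject.

    BMI is taken from the record when given, otherwise computed from height
    and weight; when all three are present they must agree to within
    0.5 kg/m².  Height and weight are optional — they are only needed by the
    Kawasaki and Tanaka creatinine sub-models.
    """

    id: str
    sex: Sex
    age: float
    bmi: float | None = None
    height: float | None = None
    weight: float | None = None
    sbp: float | None = None
    dbp: float | None = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        bmi = self.bmi
        if bmi is None:
            if self.height is None or self.weight is None:
                raise ValueError("need bmi, or height and weight to derive it")
            bmi = self.weight / (self.height / 100.0) ** 2
            object.__setattr__(self, "bmi", bmi)
        if bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.height is not None and self.weight is not None:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(bmi - implied) > BMI_CONSISTENCY_TOL:
                raise ValueError(
                    f"bmi {bmi:.2f} inconsistent with height/weight "
                    f"(implied {implied:.2f}, tolerance {BMI_CONSISTENCY_TOL})"
                )


@dataclass(frozen=True)
class EstimateResult:
    """Per-method estimates for one record.

    ``prucr24h`` (mg/day) is the Kawasaki/Tanaka intermediate.  When a method
    cannot be evaluated the reason is recorded in ``missing`` instead of the
    record being dropped silently.  Negative linear-formula outputs are
    returned as-is with a warning flag, never clipped.
    """

    method: EstimatorId
    est_na: float | None = None
    est_k: float | None = None
    prucr24h: float | None = None
    missing: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# unit conversions
# --------------------------------------------------------------------------

def cr_mmol_to_mg(cr):
    """Convert a creatinine concentration from mmol/L to mg/L.

    Multiplies by the creatinine molar mass, 113.12 g/mol.  Accepts scalars
    or arrays; negative input is a domain error.
    """
    cr = np.asarray(cr, dtype=float)
    if np.any(cr < 0):
        raise ValueError("creatinine concentration must be non-negative")
    out = cr * CREATININE_MG_PER_MMOL
    return float(out) if out.ndim == 0 else out


def na_mmol_to_g_salt(na):
    """Convert mmol of sodium to grams of NaCl (factor 0.05844 g/mmol).

    Rounding is left to the caller; 17.1 mmol Na is the conventional 1 g of
    salt.
    """
    na = np.asarray(na, dtype=float)
    if np.any(na < 0):
        raise ValueError("sodium amount must be non-negative")
    out = na * NACL_G_PER_MMOL_NA
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# the new sex-specific formulas
# --------------------------------------------------------------------------

def _as_float(x):
    x = np.asarray(x, dtype=float)
    return float(x) if x.ndim == 0 else x


def estimate_na_new(sex: Sex, age, bmi, spot: SpotSpecimen | None = None,
                    *, spot_na=None, spot_cr=None):
    """Estimated 24 h urinary sodium excretion (mmol/day), new formula.

    Linear in age, BMI, spot Na (mmol/L) and the spot Na/Cr ratio with both
    concentrations in mmol/L.  Scalar or array inputs; pass either a
    :class:`SpotSpecimen` or the ``spot_na``/``spot_cr`` keywords.
    """
    if spot is not None:
        spot_na, spot_cr = spot.na, spot.cr
    spot_na = np.asarray(spot_na, dtype=float)
    spot_cr = np.asarray(spot_cr, dtype=float)
    if np.any(spot_cr <= 0):
        raise ValueError("spot creatinine must be strictly positive")
    c = COEFFICIENTS["new"]["na"][Sex.parse(sex)]
    out = (c["intercept"] + c["age"] * np.asarray(age, dtype=float)
           + c["bmi"] * np.asarray(bmi, dtype=float)
           + c["spot_na"] * spot_na + c["na_cr_ratio"] * (spot_na / spot_cr))
    return _as_float(out)


def estimate_k_new(sex: Sex, age, bmi, spot: SpotSpecimen | None = None,
                   *, spot_k=None, spot_na=None, spot_cr=None):
    """Estimated 24 h urinary potassium excretion (mmol/day), new formula.

    Linear in age, BMI, spot K, ln(spot K / spot Cr) and ln(spot Na /
    spot Cr); all concentrations in mmol/L.  Requires strictly positive
    na, k and cr (natural logs of both ratios).
    """
    if spot is not None:
        spot_k, spot_na, spot_cr = spot.k, spot.na, spot.cr
    spot_k = np.asarray(spot_k, dtype=float)
    spot_na = np.asarray(spot_na, dtype=float)
    spot_cr = np.asarray(spot_cr, dtype=float)
    if np.any(spot_cr <= 0) or np.any(spot_na <= 0) or np.any(spot_k <= 0):
        raise ValueError("spot na, k and cr must be strictly positive (log ratios)")
    c = COEFFICIENTS["new"]["k"][Sex.parse(sex)]
    out = (c["intercept"] + c["age"] * np.asarray(age, dtype=float)
           + c["bmi"] * np.asarray(bmi, dtype=float)
           + c["spot_k"] * spot_k
           + c["ln_k_cr"] * np.log(spot_k / spot_cr)
           + c["ln_na_cr"] * np.log(spot_na / spot_cr))
    return _as_float(out)


# --------------------------------------------------------------------------
# published comparator formulas
# --------------------------------------------------------------------------

def predict_creatinine_kawasaki(sex: Sex, weight, height, age):
    """Kawasaki predicted 24 h urinary creatinine excretion (mg/day).

    Sex-specific linear model in weight (kg), height (cm) and age (years).
    A non-positive prediction means the anthropometry is outside the
    formula's domain and raises.
    """
    c = COEFFICIENTS["kawasaki"]["prucr"][Sex.parse(sex)]
    out = (c["weight"] * np.asarray(weight, dtype=float)
           + c["height"] * np.asarray(height, dtype=float)
           + c["age"] * np.asarray(age, dtype=float) + c["intercept"])
    if np.any(np.asarray(out) <= 0):
        raise ValueError("predicted 24 h creatinine is non-positive; "
                         "anthropometry outside the formula's domain")
    return _as_float(out)


def predict_creatinine_tanaka(weight, height, age):
    """Tanaka predicted 24 h urinary creatinine excretion (mg/day), sex-free."""
    c = COEFFICIENTS["tanaka"]["prucr"]
    out = (c["weight"] * np.asarray(weight, dtype=float)
           + c["height"] * np.asarray(height, dtype=float)
           + c["age"] * np.asarray(age, dtype=float) + c["intercept"])
    if np.any(np.asarray(out) <= 0):
        raise ValueError("predicted 24 h creatinine is non-positive; "
                         "anthropometry outside the formula's domain")
    return _as_float(out)


def _ratio_power_estimate(registry: dict, analyte: str, spot_conc, spot_cr_mmol,
                          prucr_mg_day):
    """const * (analyte / cr_mg_per_L * PrUCr24h) ** exponent."""
    spot_conc = np.asarray(spot_conc, dtype=float)
    spot_cr_mmol = np.asarray(spot_cr_mmol, dtype=float)
    if np.any(spot_conc < 0):
        raise ValueError("analyte concentration must be non-negative")
    if np.any(spot_cr_mmol <= 0):
        raise ValueError("spot creatinine must be strictly positive")
    cr_mg = cr_mmol_to_mg(spot_cr_mmol)
    x = spot_conc / cr_mg * np.asarray(prucr_mg_day, dtype=float)
    p = registry[analyte]
    return _as_float(p["const"] * np.power(x, p["exponent"]))


def estimate_kawasaki(sex: Sex, weight, height, age, spot: SpotSpecimen | None = None,
                      analyte: str = "na", *, spot_conc=None, spot_cr=None):
    """Kawasaki estimate of 24 h Na or K excretion (mmol/day).

    ``const * sqrt(spot_conc (mmol/L) / spot_cr (mg/L) * PrUCr24h (mg/day))``
    with const 16.30 for sodium and 7.20 for potassium.
    """
    analyte = analyte.lower()
    if analyte not in ("na", "k"):
        raise ValueError("analyte must be 'na' or 'k'")
    if spot is not None:
        spot_conc = spot.na if analyte == "na" else spot.k
        spot_cr = spot.cr
    prucr = predict_creatinine_kawasaki(sex, weight, height, age)
    return _ratio_power_estimate(COEFFICIENTS["kawasaki"], analyte,
                                 spot_conc, spot_cr, prucr)


def estimate_tanaka(weight, height, age, spot: SpotSpecimen | None = None,
                    analyte: str = "na", *, spot_conc=None, spot_cr=None):
    """Tanaka estimate of 24 h Na or K excretion (mmol/day).

    ``21.98 * x**0.392`` for sodium, ``7.59 * x**0.431`` for potassium, with
    ``x = spot_conc (mmol/L) / spot_cr (mg/L) * PrUCr24h (mg/day)``.
    """
    analyte = analyte.lower()
    if analyte not in ("na", "k"):
        raise ValueError("analyte must be 'na' or 'k'")
    if spot is not None:
        spot_conc = spot.na if analyte == "na" else spot.k
        spot_cr = spot.cr
    prucr = predict_creatinine_tanaka(weight, height, age)
    return _ratio_power_estimate(COEFFICIENTS["tanaka"], analyte,
                                 spot_conc, spot_cr, prucr)


def estimate_na_intersalt(sex: Sex, age, bmi, spot: SpotSpecimen | None = None,
                          *, spot_na=None, spot_k=None, spot_cr=None):
    """INTERSALT estimate of 24 h sodium excretion (mmol/day).

    Linear in spot Na, spot Cr (kept in mmol/L — no unit conversion), spot K,
    BMI and age; the female equation carries an additional age² term.
    """
    if spot is not None:
        spot_na, spot_k, spot_cr = spot.na, spot.k, spot.cr
    spot_na = np.asarray(spot_na, dtype=float)
    spot_k = np.asarray(spot_k, dtype=float)
    spot_cr = np.asarray(spot_cr, dtype=float)
    if np.any(spot_na < 0) or np.any(spot_k < 0) or np.any(spot_cr < 0):
        raise ValueError("spot concentrations must be non-negative")
    age = np.asarray(age, dtype=float)
    c = COEFFICIENTS["intersalt"]["na"][Sex.parse(sex)]
    out = (c["intercept"] + c["spot_na"] * spot_na + c["spot_cr"] * spot_cr
           + c["spot_k"] * spot_k + c["bmi"] * np.asarray(bmi, dtype=float)
           + c["age"] * age + c["age2"] * age ** 2)
    return _as_float(out)


# --------------------------------------------------------------------------
# per-record dispatch
# --------------------------------------------------------------------------

def estimate_all(record: ParticipantRecord, spot: SpotSpecimen,
                 methods: Sequence[EstimatorId] | None = None) -> list[EstimateResult]:
    """Evaluate every applicable formula for one record.

    Methods whose inputs are missing (e.g. Kawasaki/Tanaka without height
    and weight) are reported with a reason rather than dropped.  INTERSALT
    never yields a potassium estimate.  Negative outputs are flagged, not
    clipped.
    """
    if methods is None:
        methods = list(EstimatorId)
    results: list[EstimateResult] = []
    for m in methods:
        missing: list[str] = []
        warns: list[str] = []
        est_na = est_k = prucr = None
        try:
            if m is EstimatorId.NEW:
                est_na = estimate_na_new(record.sex, record.age, record.bmi, spot)
                if spot.na > 0 and spot.k > 0:
                    est_k = estimate_k_new(record.sex, record.age, record.bmi, spot)
                else:
                    missing.append("k: non-positive spot na or k (log ratio undefined)")
            elif m is EstimatorId.INTERSALT:
                est_na = estimate_na_intersalt(record.sex, record.age, record.bmi, spot)
                missing.append("k: no INTERSALT potassium equation")
            elif m in (EstimatorId.KAWASAKI, EstimatorId.TANAKA):
                if record.height is None or record.weight is None:
                    missing.append("na: height/weight required")
                    missing.append("k: height/weight required")
                elif m is EstimatorId.KAWASAKI:
                    prucr = predict_creatinine_kawasaki(
                        record.sex, record.weight, record.height, record.age)
                    est_na = estimate_kawasaki(record.sex, record.weight,
                                               record.height, record.age, spot, "na")
                    est_k = estimate_kawasaki(record.sex, record.weight,
                                              record.height, record.age, spot, "k")
                else:
                    prucr = predict_creatinine_tanaka(
                        record.weight, record.height, record.age)
                    est_na = estimate_tanaka(record.weight, record.height,
                                             record.age, spot, "na")
                    est_k = estimate_tanaka(record.weight, record.height,
                                            record.age, spot, "k")
        except ValueError as exc:
            missing.append(f"domain error: {exc}")
            est_na = est_k = prucr = None
        for label, v in (("na", est_na), ("k", est_k)):
            if v is not None and v < 0:
                warns.append(f"negative {label} estimate returned unclipped")
        results.append(EstimateResult(method=m, est_na=est_na, est_k=est_k,
                                      prucr24h=prucr, missing=tuple(missing),
                                      warnings=tuple(warns)))
    return results


# --------------------------------------------------------------------------
# batch (DataFrame / delimited-text) interface
# --------------------------------------------------------------------------

#: canonical cohort schema; measured 24 h columns are optional on input.
COHORT_COLUMNS = [
    "id", "sex", "age_y", "height_cm", "weight_kg", "bmi",
    "spot_na_mmol_l", "spot_k_mmol_l", "spot_cr_mmol_l",
    "u24_vol_l", "u24_na_mmol", "u24_k_mmol", "u24_cr_mmol", "missed_l",
]

_REQUIRED_COLUMNS = ["id", "sex", "age_y", "bmi",
                     "spot_na_mmol_l", "spot_k_mmol_l", "spot_cr_mmol_l"]


def _validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    bad_sex = ~df["sex"].astype(str).str.upper().isin(["M", "F", "MALE", "FEMALE"])
    if bad_sex.any():
        raise ValueError(f"unparseable sex values: {df.loc[bad_sex, 'sex'].unique()}")
    if (df["spot_cr_mmol_l"] <= 0).any():
        raise ValueError("spot creatinine must be strictly positive for every record")
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort from comma-separated text (header row, empty = missing)."""
    return _validate_cohort(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort (or any derived table) as comma-separated text."""
    df.to_csv(path, index=False)


def estimate_batch(df: pd.DataFrame,
                   methods: Sequence[EstimatorId] | None = None) -> pd.DataFrame:
    """Vectorised estimates for a cohort table.

    Returns a copy of ``df`` with ``est_na_<method>``, ``est_k_<method>`` and
    ``prucr24h_<method>`` columns appended.  Records lacking the inputs of a
    method (missing height/weight for Kawasaki/Tanaka; non-positive spot Na
    or K for the new potassium formula) get NaN in the affected columns.
    """
    df = _validate_cohort(df).copy()
    if methods is None:
        methods = list(EstimatorId)
    male = df["sex"].astype(str).str.upper().str.startswith("M").to_numpy()
    age = df["age_y"].to_numpy(float)
    bmi = df["bmi"].to_numpy(float)
    na = df["spot_na_mmol_l"].to_numpy(float)
    k = df["spot_k_mmol_l"].to_numpy(float)
    cr = df["spot_cr_mmol_l"].to_numpy(float)
    height = df["height_cm"].to_numpy(float) if "height_cm" in df else np.full(len(df), np.nan)
    weight = df["weight_kg"].to_numpy(float) if "weight_kg" in df else np.full(len(df), np.nan)

    def per_sex(fn_by_sex):
        out = np.full(len(df), np.nan)
        for is_male, sex in ((male, Sex.MALE), (~male, Sex.FEMALE)):
            if is_male.any():
                out[is_male] = fn_by_sex(sex, is_male)
        return out

    for m in methods:
        key = m.value
        if m is EstimatorId.NEW:
            df[f"est_na_{key}"] = per_sex(
                lambda s, i: estimate_na_new(s, age[i], bmi[i],
                                             spot_na=na[i], spot_cr=cr[i]))
            ok = (na > 0) & (k > 0)
            est_k = np.full(len(df), np.nan)
            for is_male, sex in ((male, Sex.MALE), (~male, Sex.FEMALE)):
                sel = is_male & ok
                if sel.any():
                    est_k[sel] = estimate_k_new(sex, age[sel], bmi[sel],
                                                spot_k=k[sel], spot_na=na[sel],
                                                spot_cr=cr[sel])
            df[f"est_k_{key}"] = est_k
        elif m is EstimatorId.INTERSALT:
            df[f"est_na_{key}"] = per_sex(
                lambda s, i: estimate_na_intersalt(s, age[i], bmi[i], spot_na=na[i],
                                                   spot_k=k[i], spot_cr=cr[i]))
        else:
            has_anthro = ~(np.isnan(height) | np.isnan(weight))
            prucr = np.full(len(df), np.nan)
            est_na = np.full(len(df), np.nan)
            est_k = np.full(len(df), np.nan)
            if m is EstimatorId.KAWASAKI:
                for is_male, sex in ((male, Sex.MALE), (~male, Sex.FEMALE)):
                    sel = is_male & has_anthro
                    if sel.any():
                        prucr[sel] = predict_creatinine_kawasaki(
                            sex, weight[sel], height[sel], age[sel])
                        est_na[sel] = estimate_kawasaki(
                            sex, weight[sel], height[sel], age[sel],
                            analyte="na", spot_conc=na[sel], spot_cr=cr[sel])
                        est_k[sel] = estimate_kawasaki(
                            sex, weight[sel], height[sel], age[sel],
                            analyte="k", spot_conc=k[sel], spot_cr=cr[sel])
            else:
                sel = has_anthro
                if sel.any():
                    prucr[sel] = predict_creatinine_tanaka(
                        weight[sel], height[sel], age[sel])
                    est_na[sel] = estimate_tanaka(
                        weight[sel], height[sel], age[sel],
                        analyte="na", spot_conc=na[sel], spot_cr=cr[sel])
                    est_k[sel] = estimate_tanaka(
                        weight[sel], height[sel], age[sel],
                        analyte="k", spot_conc=k[sel], spot_cr=cr[sel])
            df[f"prucr24h_{key}"] = prucr
            df[f"est_na_{key}"] = est_na
            df[f"est_k_{key}"] = est_k
    return df
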