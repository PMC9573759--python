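"""Development of the sex-specific estimating equations.

The development step is deliberately plain: a single random 70/30
train/test split, then per-sex, per-outcome stepwise multiple linear
regression of the measured 24 h excretion on a small candidate set of
spot-urine terms, followed by an ordinary-least-squares refit of the
retained terms.  Selection enters a term when its partial-F p value is
below ``entry_p`` (default 0.05) and removes one when it rises above
``stay_p`` (default 0.10) — the classic SPSS stepwise defaults.  For a
single added term the partial F equals the squared t of its coefficient,
so the implementation tests coefficients directly.

Candidate terms are derived from the canonical cohort columns:

========== ======================================
term        definition
========== ======================================
age         age_y (years)
bmi         bmi (kg/m²)
spot_na     spot sodium, mmol/L
spot_k      spot potassium, mmol/L
na_cr_ratio spot_na / spot_cr (both mmol/L)
ln_k_cr     ln(spot_k / spot_cr)
ln_na_cr    ln(spot_na / spot_cr)
========== ======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import Sex

__all__ = ["ModelSpec", "FittedModel", "TERM_DEFINITIONS", "PAPER_TERMS",
           "OUTCOME_COLUMNS", "candidate_matrix", "split_train_test",
           "stepwise_fit", "fit_paper_models"]

#: design condition-number ceiling beyond which a candidate is refused
CONDITION_NUMBER_MAX = 1e10

TERM_DEFINITIONS = {
    "age": lambda d: d["age_y"].astype(float),
    "bmi": lambda d: d["bmi"].astype(float),
    "spot_na": lambda d: d["spot_na_mmol_l"].astype(float),
    "spot_k": lambda d: d["spot_k_mmol_l"].astype(float),
    "na_cr_ratio": lambda d: d["spot_na_mmol_l"] / d["spot_cr_mmol_l"],
    "ln_k_cr": lambda d: np.log(d["spot_k_mmol_l"] / d["spot_cr_mmol_l"]),
    "ln_na_cr": lambda d: np.log(d["spot_na_mmol_l"] / d["spot_cr_mmol_l"]),
}

#: final published term sets, per outcome
PAPER_TERMS = {
    "na24": ["age", "bmi", "spot_na", "na_cr_ratio"],
    "k24": ["age", "bmi", "spot_k", "ln_k_cr", "ln_na_cr"],
}

OUTCOME_COLUMNS = {"na24": "u24_na_mmol", "k24": "u24_k_mmol"}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, sex stratum, candidate terms, and thresholds."""

    outcome: str                      # "na24" or "k24"
    sex: Sex | None = None
    candidate_terms: tuple[str, ...] = ()
    entry_p: float = 0.05
    stay_p: float = 0.10

    def __post_init__(self):
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.entry_p <= self.stay_p:
            raise ValueError("entry_p must not exceed stay_p")
        unknown = [t for t in self.candidate_terms if t not in TERM_DEFINITIONS]
        if unknown:
            raise ValueError(f"unknown candidate terms: {unknown}")


@dataclass
class FittedModel:
    """An estimating equation with its coefficient table.

    ``table`` has one row per term ('intercept' first): coefficient,
    standard error, t statistic and two-sided p value.  ``r`` is the
    multiple correlation of the fit on its own training data.
    """

    spec: ModelSpec
    table: pd.DataFrame
    r: float
    n: int
    warnings: list = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table["term"] if t != "intercept"]

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = candidate_matrix(df, self.terms)
        coefs = self.table.set_index("term")["coef"]
        out = np.full(len(df), coefs.get("intercept", 0.0))
        for t in self.terms:
            out = out + coefs[t] * X[t].to_numpy(float)
        return out

    def to_text(self) -> str:
        sex = self.spec.sex.name.lower() if self.spec.sex else "pooled"
        head = f"model {self.spec.outcome} / {sex}   n={self.n}   R={self.r:.3f}"
        body = self.table.to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}")
        warn = "".join(f"\nwarning: {w}" for w in self.warnings)
        return f"{head}\n{body}{warn}"

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "outcome", self.spec.outcome)
        out.insert(1, "sex", self.spec.sex.value if self.spec.sex else "")
        out["r"] = self.r
        out["n"] = self.n
        return out


def candidate_matrix(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Compute the requested candidate terms from canonical cohort columns."""
    return pd.DataFrame({t: TERM_DEFINITIONS[t](df) for t in terms},
                        index=df.index)


def split_train_test(records: pd.DataFrame, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random train/test partition without replacement.

    The training size is ``round(n * train_fraction)`` (banker's rounding);
    the partition is disjoint, exhaustive and reproducible from ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = records.iloc[np.sort(perm[:n_train])].copy()
    test = records.iloc[np.sort(perm[n_train:])].copy()
    return train, test


def _ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X.to_numpy(float), has_constant="add")
    return sm.OLS(y, design).fit()


def _design_admissible(Xtry: pd.DataFrame) -> bool:
    """Reject designs with a (near-)constant column or severe collinearity."""
    last = Xtry.iloc[:, -1].to_numpy(float)
    if last.std() <= 1e-9 * max(1.0, abs(last.mean())):
        return False
    std = Xtry.std(ddof=0).replace(0, 1)
    design = sm.add_constant(((Xtry - Xtry.mean()) / std).to_numpy(float),
                             has_constant="add")
    return np.linalg.cond(design) <= CONDITION_NUMBER_MAX


def stepwise_fit(train: pd.DataFrame, spec: ModelSpec,
                 y: np.ndarray | None = None) -> FittedModel:
    """Forward-selection / backward-elimination fit with an OLS refit.

    Terms enter when the p value of their coefficient (equivalently the
    partial-F p for a single term) is below ``spec.entry_p`` and leave when
    it exceeds ``spec.stay_p``; iteration stops when a pass changes nothing
    or a term set repeats.  Candidates that would push the design's
    condition number above 1e10 are refused with a warning.  When nothing
    enters, the intercept-only model is returned with a warning.
    """
    ycol = OUTCOME_COLUMNS[spec.outcome]
    if y is None:
        y = train[ycol].to_numpy(float)
    else:
        y = np.asarray(y, float)
    candidates = list(spec.candidate_terms)
    if len(train) < len(candidates) + 2:
        raise ValueError("too few records for the candidate set")
    Xall = candidate_matrix(train, candidates)
    warnings: list[str] = []

    selected: list[str] = []
    seen = {tuple()}
    while True:
        changed = False
        # forward step: best admissible candidate below entry_p
        best_p, best_term = None, None
        for t in candidates:
            if t in selected:
                continue
            Xtry = Xall[selected + [t]]
            if not _design_admissible(Xtry):
                if f"collinear candidate refused: {t}" not in warnings:
                    warnings.append(f"collinear candidate refused: {t}")
                continue
            res = _ols(y, Xtry)
            p = res.pvalues[-1]
            if p < spec.entry_p and (best_p is None or p < best_p):
                best_p, best_term = p, t
        if best_term is not None:
            selected.append(best_term)
            changed = True
        # backward step: worst retained term above stay_p
        while selected:
            res = _ols(y, Xall[selected])
            pvals = pd.Series(res.pvalues[1:], index=selected)
            worst = pvals.idxmax()
            if pvals[worst] > spec.stay_p:
                selected.remove(worst)
                changed = True
            else:
                break
        key = tuple(selected)
        if not changed or key in seen:
            break
        seen.add(key)

    if not selected:
        warnings.append("no term met the entry criterion; intercept-only model")
    res = _ols(y, Xall[selected]) if selected else sm.OLS(
        y, np.ones((len(y), 1))).fit()
    return _pack(res, selected, spec, len(y), warnings)


def _pack(res, terms, spec, n, warnings) -> FittedModel:
    names = ["intercept"] + list(terms)
    table = pd.DataFrame({
        "term": names,
        "coef": np.asarray(res.params, float),
        "se": np.asarray(res.bse, float),
        "t": np.asarray(res.tvalues, float),
        "p": np.asarray(res.pvalues, float),
    })
    r = float(np.sqrt(max(res.rsquared, 0.0))) if terms else 0.0
    return FittedModel(spec=spec, table=table, r=r, n=n, warnings=list(warnings))


def ols_fit(train: pd.DataFrame, spec: ModelSpec,
            y: np.ndarray | None = None) -> FittedModel:
    """Plain OLS on the full candidate set (selection disabled).

    Terms that are collinear with the existing design (condition number
    above 1e10 on the standardized design) are dropped with a warning.
    """
    ycol = OUTCOME_COLUMNS[spec.outcome]
    if y is None:
        y = train[ycol].to_numpy(float)
    else:
        y = np.asarray(y, float)
    warnings: list[str] = []
    kept: list[str] = []
    for t in spec.candidate_terms:
        if not _design_admissible(candidate_matrix(train, kept + [t])):
            warnings.append(f"collinear term dropped: {t}")
            continue
        kept.append(t)
    res = _ols(y, candidate_matrix(train, kept)) if kept else sm.OLS(
        y, np.ones((len(y), 1))).fit()
    return _pack(res, kept, spec, len(y), warnings)


def fit_paper_models(train: pd.DataFrame, *, stepwise: bool = False,
                     entry_p: float = 0.05, stay_p: float = 0.10
                     ) -> dict[tuple[str, Sex], FittedModel]:
    """Fit the four published-shape models (Na/K × male/female).

    Uses exactly the published term sets (sodium: age, bmi, spot_na,
    na_cr_ratio; potassium: age, bmi, spot_k, ln_k_cr, ln_na_cr).  With
    ``stepwise=True`` selection runs first and any published term that
    selection removes is reported in the model's warnings rather than
    treated as an error.  A single-sex input yields a partial result with a
    warning attached to the returned mapping via the absent keys.
    """
    is_male = train["sex"].astype(str).str.upper().str.startswith("M")
    models: dict[tuple[str, Sex], FittedModel] = {}
    for sex, mask in ((Sex.MALE, is_male), (Sex.FEMALE, ~is_male)):
        sub = train[mask.to_numpy()]
        for outcome, terms in PAPER_TERMS.items():
            spec = ModelSpec(outcome=outcome, sex=sex,
                             candidate_terms=tuple(terms),
                             entry_p=entry_p, stay_p=stay_p)
            if len(sub) < len(terms) + 2:
                continue
            if stepwise:
                fm = stepwise_fit(sub, spec)
                dropped = [t for t in terms if t not in fm.terms]
                if dropped:
                    fm.warnings.append(
                        f"selection removed published terms: {dropped}")
            else:
                fm = ols_fit(sub, spec)
            models[(outcome, sex)] = fm
    return models


def models_to_frame(models: dict) -> pd.DataFrame:
    """Stack fitted models into one machine-readable coefficient table."""
    if not models:
        return pd.DataFrame(columns=["outcome", "sex", "term", "coef", "se",
                                     "t", "p", "r", "n"])
    return pd.concat([m.to_frame() for m in models.values()], ignore_index=True)
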