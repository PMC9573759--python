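"""Agreement statistics between measured and estimated 24 h excretion.

A spot-urine formula is judged at two levels.  At the population level:
mean bias (estimated − measured) with a t-based 95 % CI and paired t test;
Pearson's r, with a test for the difference between two formulas' r against
the same measured series (dependent overlapping correlations, the
Hittner–May–Silver modification of Dunn & Clark's z); and the intraclass
correlation ICC(A,1) — two-way model, single measures, absolute agreement —
which, unlike Pearson's r, penalises systematic offsets.  At the individual
level: the P30 (share of estimates within ±30 % of the measured value) and
general within-cutoff proportions, relative or absolute, plus Bland–Altman
bias and 1.96-SD limits of agreement with exportable (mean, difference)
pairs.

``validate_all`` assembles these per (analyte, formula) into a summary
table; ``sample_size_correlation`` is the Fisher-z planning calculation for
detecting a non-zero correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimatorId, estimate_batch

__all__ = ["PairedSeries", "ValidationMetrics", "mean_bias_ci",
           "pearson_with_comparison", "icc_a1", "p30", "proportion_within",
           "proportion_curve", "bland_altman", "validate_all",
           "sample_size_correlation", "DEFAULT_CUTOFFS"]

#: individual-level cutoffs reported alongside P30: ±10 % relative and the
#: analyte-specific absolute bands (mmol/day).
DEFAULT_CUTOFFS = {"na": [("relative", 0.10), ("relative", 0.30), ("absolute", 17.1)],
                   "k": [("relative", 0.10), ("relative", 0.30), ("absolute", 12.8)]}


@dataclass
class PairedSeries:
    """Measured/estimated pairs for one formula and analyte."""

    measured: np.ndarray
    estimated: np.ndarray
    method: EstimatorId | str = ""
    analyte: str = ""

    def __post_init__(self):
        self.measured = np.asarray(self.measured, float)
        self.estimated = np.asarray(self.estimated, float)
        if self.measured.shape != self.estimated.shape:
            raise ValueError("measured and estimated must have equal length")
        if np.isnan(self.measured).any() or np.isnan(self.estimated).any():
            raise ValueError("missing values must be removed before pairing")

    def __len__(self):
        return len(self.measured)


@dataclass
class ValidationMetrics:
    """One formula's agreement summary (one table row)."""

    method: str
    analyte: str
    n: int
    est_mean: float
    est_sd: float
    bias: float
    bias_ci: tuple[float, float]
    paired_t_p: float
    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci: tuple[float, float]
    icc_band: str
    p30: float
    cutoff_table: list = field(default_factory=list)
    r_comparison_p: float | None = None
    bias_comparison_p: float | None = None

    def significance_markers(self, alpha: float = 0.05) -> str:
        """'a' = differs from measured (paired t); 'b' = differs from the
        reference formula (correlation comparison or bias-difference)."""
        marks = ""
        if self.paired_t_p <= alpha:
            marks += "a"
        ps = [p for p in (self.r_comparison_p, self.bias_comparison_p) if p is not None]
        if any(p <= alpha for p in ps):
            marks += "b"
        return marks


# --------------------------------------------------------------------------
# population-level agreement
# --------------------------------------------------------------------------

def mean_bias_ci(p: PairedSeries, level: float = 0.95):
    """Mean bias (estimated − measured) with t-based CI and paired-t p value.

    Zero-variance differences degenerate: the CI collapses to the point and
    the p value is reported as 1.0 when the bias is exactly zero (exact
    agreement) or 0.0 otherwise.
    """
    n = len(p)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = p.estimated - p.measured
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return bias, (bias, bias), (1.0 if bias == 0.0 else 0.0)
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
    tstat = bias / se
    pval = 2 * stats.t.sf(abs(tstat), n - 1)
    return bias, (bias - tcrit * se, bias + tcrit * se), float(pval)


def _hittner_may_silver(r12: float, r13: float, r23: float, n: int):
    """Dunn–Clark z for dependent overlapping correlations, using the
    back-transformed average correlation (Hittner–May–Silver / Steiger)."""
    # clamp away from |r| = 1 so the Fisher transform stays finite
    r12 = float(np.clip(r12, -1 + 1e-12, 1 - 1e-12))
    r13 = float(np.clip(r13, -1 + 1e-12, 1 - 1e-12))
    r23 = float(np.clip(r23, -1 + 1e-12, 1 - 1e-12))
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = np.tanh((z12 + z13) / 2)       # back-transformed average
    num = r23 * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r23 ** 2)
    c = num / (1 - rbar ** 2) ** 2
    # c can exceed 1 when a correlation sits at the boundary (degenerate
    # sampling variance); cap it so the statistic stays defined and the
    # boundary case yields an extreme z rather than a crash
    c = min(c, 1 - 1e-8)
    z = (z12 - z13) * math.sqrt((n - 3) / (2 - 2 * c))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def pearson_with_comparison(measured, est_a, est_b):
    """Pearson r of two formulas against the same measured series, plus a
    two-sided test of r_A = r_B for dependent overlapping correlations.

    Returns ``(r_a, r_b, z, p)``.  Requires n ≥ 10 and non-constant inputs.
    """
    measured = np.asarray(measured, float)
    est_a = np.asarray(est_a, float)
    est_b = np.asarray(est_b, float)
    n = len(measured)
    if n < 10:
        raise ValueError("need at least 10 pairs to compare correlations")
    for v in (measured, est_a, est_b):
        if np.std(v) == 0:
            raise ValueError("correlation undefined for a constant vector")
    r_a = float(stats.pearsonr(measured, est_a).statistic)
    r_b = float(stats.pearsonr(measured, est_b).statistic)
    r_ab = float(stats.pearsonr(est_a, est_b).statistic)
    if np.allclose(est_a, est_b):
        return r_a, r_b, 0.0, 1.0
    z, p = _hittner_may_silver(r_a, r_b, r_ab, n)
    return r_a, r_b, z, p


def _icc_bands(icc: float) -> str:
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def icc_a1(p: PairedSeries, level: float = 0.95):
    """ICC(A,1): two-way model, single measures, absolute agreement.

    With n subjects rated by k = 2 fixed "raters" (measured, estimated):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    where MSR, MSC and MSE are the rows (subjects), columns (raters) and
    error mean squares of the two-way ANOVA.  The confidence interval is the
    F-based procedure of McGraw & Wong.  Returns ``(icc, (lo, hi), band)``
    with a qualitative reliability band (moderate 0.50–0.75, good
    0.75–0.90, excellent > 0.90).  Zero between-subject variance leaves the
    coefficient undefined.
    """
    n = len(p)
    if n < 5:
        raise ValueError("need at least 5 pairs")
    data = np.column_stack([p.measured, p.estimated])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0 or ssr == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1 - level
    if mse == 0 and msc == 0:
        ci = (icc, icc)
    else:
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if not np.isfinite(a):
            ci = (1.0, 1.0)
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_lo * mse) / (
                f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_hi * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_hi * msr)
            ci = (float(lo), float(hi))
    return float(icc), ci, _icc_bands(float(icc))


# --------------------------------------------------------------------------
# individual-level accuracy
# --------------------------------------------------------------------------

def proportion_within(p: PairedSeries, mode: str, cutoff: float) -> float:
    """Percentage of pairs whose difference is within ``cutoff``.

    ``mode='relative'``: |est − meas| / meas ≤ cutoff (measured must be
    positive); ``mode='absolute'``: |est − meas| ≤ cutoff (mmol/day).
    Boundaries are inclusive.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    diff = np.abs(p.estimated - p.measured)
    if mode == "relative":
        if np.any(p.measured <= 0):
            raise ValueError("relative mode requires positive measured values")
        within = diff / p.measured <= cutoff
    elif mode == "absolute":
        within = diff <= cutoff
    else:
        raise ValueError("mode must be 'relative' or 'absolute'")
    return float(100.0 * within.mean())


def p30(p: PairedSeries) -> float:
    """P30: percentage of estimates within ±30 % of the measured value."""
    return proportion_within(p, "relative", 0.30)


def proportion_curve(p: PairedSeries, mode: str, cutoffs) -> pd.DataFrame:
    """Within-cutoff percentage over a grid, for appendix-style curves."""
    return pd.DataFrame({
        "mode": mode,
        "cutoff": list(cutoffs),
        "pct_within": [proportion_within(p, mode, c) for c in cutoffs],
    })


def bland_altman(p: PairedSeries):
    """Bland–Altman bias and 1.96-SD limits of agreement.

    Differences are estimated − measured.  Returns ``(bias, loa_low,
    loa_high, pairs)`` where ``pairs`` is a DataFrame of the per-record
    plotting coordinates (mean of the two values, difference).
    """
    if len(p) < 3:
        raise ValueError("need at least 3 pairs")
    diff = p.estimated - p.measured
    mean = (p.estimated + p.measured) / 2
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pairs = pd.DataFrame({"mean": mean, "diff": diff})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, pairs


# --------------------------------------------------------------------------
# the full comparison table
# --------------------------------------------------------------------------

_METHODS_BY_ANALYTE = {
    "na": [EstimatorId.NEW, EstimatorId.KAWASAKI, EstimatorId.INTERSALT,
           EstimatorId.TANAKA],
    "k": [EstimatorId.NEW, EstimatorId.KAWASAKI, EstimatorId.TANAKA],
}


def validate_all(records: pd.DataFrame,
                 reference: EstimatorId = EstimatorId.NEW,
                 methods_by_analyte: dict | None = None,
                 cutoffs: dict | None = None) -> list[ValidationMetrics]:
    """Full per-(analyte, formula) agreement table for a test cohort.

    ``records`` must carry measured ``u24_na_mmol``/``u24_k_mmol`` plus the
    covariates the formulas need; estimates are computed here.  Records with
    a missing estimate for a formula are dropped pairwise for that formula
    only, and records whose measured value is not strictly positive are
    dropped for that analyte (relative-difference metrics are undefined for
    them); the per-row ``n`` makes every deletion explicit.  The
    correlation-difference and bias-difference tests compare each formula
    against ``reference`` on their common records.
    """
    methods_by_analyte = methods_by_analyte or _METHODS_BY_ANALYTE
    cutoffs = cutoffs or DEFAULT_CUTOFFS
    est = estimate_batch(records)
    out: list[ValidationMetrics] = []
    for analyte, methods in methods_by_analyte.items():
        meas_col = "u24_na_mmol" if analyte == "na" else "u24_k_mmol"
        measured = est[meas_col].to_numpy(float)
        ref_col = f"est_{analyte}_{reference.value}"
        ref_vals = est[ref_col].to_numpy(float) if ref_col in est else None
        for m in methods:
            col = f"est_{analyte}_{m.value}"
            if col not in est:
                continue
            vals = est[col].to_numpy(float)
            ok = ~(np.isnan(vals) | np.isnan(measured)) & (measured > 0)
            series = PairedSeries(measured[ok], vals[ok], method=m.value,
                                  analyte=analyte)
            bias, ci, t_p = mean_bias_ci(series)
            r, r_p = stats.pearsonr(series.measured, series.estimated)
            icc, icc_ci, band = icc_a1(series)
            metrics = ValidationMetrics(
                method=m.value, analyte=analyte, n=len(series),
                est_mean=float(series.estimated.mean()),
                est_sd=float(series.estimated.std(ddof=1)),
                bias=bias, bias_ci=ci, paired_t_p=t_p,
                pearson_r=float(r), pearson_p=float(r_p),
                icc=icc, icc_ci=icc_ci, icc_band=band,
                p30=p30(series),
                cutoff_table=[(mode, c, proportion_within(series, mode, c))
                              for mode, c in cutoffs[analyte]],
            )
            if ref_vals is not None and m is not reference:
                both = ok & ~np.isnan(ref_vals)
                if both.sum() >= 10:
                    _, _, _, metrics.r_comparison_p = pearson_with_comparison(
                        measured[both], ref_vals[both], vals[both])
                    # bias-difference: paired t on the two error series,
                    # equivalently on est_ref - est_m
                    d = ref_vals[both] - vals[both]
                    if d.std(ddof=1) > 0:
                        metrics.bias_comparison_p = float(
                            stats.ttest_1samp(d, 0.0).pvalue)
                    else:
                        metrics.bias_comparison_p = 1.0 if d.mean() == 0 else 0.0
            out.append(metrics)
    return out


def metrics_to_frame(metrics: list[ValidationMetrics]) -> pd.DataFrame:
    """Summary rows (one per analyte × formula) as a flat table."""
    rows = []
    for m in metrics:
        rows.append({
            "analyte": m.analyte, "method": m.method, "n": m.n,
            "est_mean": m.est_mean, "est_sd": m.est_sd,
            "bias": m.bias, "bias_ci_lo": m.bias_ci[0], "bias_ci_hi": m.bias_ci[1],
            "paired_t_p": m.paired_t_p,
            "pearson_r": m.pearson_r, "pearson_p": m.pearson_p,
            "icc": m.icc, "icc_ci_lo": m.icc_ci[0], "icc_ci_hi": m.icc_ci[1],
            "icc_band": m.icc_band, "p30": m.p30,
            "r_comparison_p": m.r_comparison_p,
            "bias_comparison_p": m.bias_comparison_p,
            "markers": m.significance_markers(),
        })
    return pd.DataFrame(rows)


def cutoffs_to_frame(metrics: list[ValidationMetrics]) -> pd.DataFrame:
    """Long-format within-cutoff proportions across all formulas."""
    rows = []
    for m in metrics:
        for mode, cutoff, pct in m.cutoff_table:
            rows.append({"analyte": m.analyte, "method": m.method,
                         "mode": mode, "cutoff": cutoff, "pct_within": pct})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# planning
# --------------------------------------------------------------------------

def sample_size_correlation(r: float, alpha: float = 0.05, power: float = 0.90,
                            exclusion_rate: float = 0.10) -> int:
    """Pairs needed to detect correlation ``r`` by the Fisher-z formula.

    ``n = ((z_{1-α/2} + z_{power}) / atanh(r))² + 3``, rounded up, then
    inflated by ``1/(1 − exclusion_rate)`` and rounded up again.
    """
    if not 0 < r < 1:
        raise ValueError("r must lie strictly in (0, 1)")
    for name, v in (("alpha", alpha), ("power", power)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    if not 0 <= exclusion_rate < 1:
        raise ValueError("exclusion_rate must lie in [0, 1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n = (z / math.atanh(r)) ** 2 + 3
    n = max(math.ceil(n), 4)
    return math.ceil(n / (1 - exclusion_rate))
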