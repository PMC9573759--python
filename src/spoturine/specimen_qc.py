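"""Urine-sample quality-control filters for paired spot / 24 h records.

Incomplete or implausible 24 h collections corrupt the reference values
against which spot-urine formulas are judged, so records are screened before
any modelling.  Five rules are applied, in order:

1. ``missed_fraction`` — the self-reported missed urine volume exceeds 20 %
   of the total volume (total = collected + missed, since the self-report
   describes urine that never reached the containers); strict inequality.
2. ``volume_low`` — the collected 24 h volume is below 0.5 L.
3. ``cr24_out_of_range`` — 24 h creatinine excretion outside [4, 25] mmol/day
   for women or [6, 30] mmol/day for men (strict: boundary values are kept).
4. ``volume_3sd`` — 24 h volume more than 3 SD from the population mean.
5. ``spotcr_3sd`` — spot creatinine concentration more than 3 SD from the
   population mean.

The 3-SD rules are two-sided and use mean/SD computed once over the records
that survive rules 1–3 (single pass, no iteration).  A record may accrue
several reason codes; the kept and excluded sets always partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QcConfig", "QcReport", "REASON_CODES", "apply_exclusions",
           "flowchart_counts"]

#: stable machine-readable reason codes, in rule order
REASON_CODES = ["missed_fraction", "volume_low", "cr24_out_of_range",
                "volume_3sd", "spotcr_3sd"]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds of the five exclusion rules (defaults as published)."""

    missed_fraction_max: float = 0.20
    volume_min: float = 0.5                      # L/day
    cr24_bounds_female: tuple[float, float] = (4.0, 25.0)   # mmol/day
    cr24_bounds_male: tuple[float, float] = (6.0, 30.0)     # mmol/day
    sd_multiplier: float = 3.0

    def __post_init__(self):
        for lo, hi in (self.cr24_bounds_female, self.cr24_bounds_male):
            if not lo < hi:
                raise ValueError("creatinine bounds must be ordered")
        if min(self.missed_fraction_max, self.volume_min, self.sd_multiplier) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class QcReport:
    """Disposition of every input record.

    ``kept`` and ``excluded`` are DataFrames; ``excluded`` carries a
    ``qc_reasons`` column (semicolon-joined codes).  ``stats`` holds the
    mean/SD actually used by the 3-SD rules; ``flags`` records degenerate
    situations such as too few survivors to estimate those statistics.
    """

    kept: pd.DataFrame
    excluded: pd.DataFrame
    counts: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        """One row per record: id, kept flag, semicolon-joined reasons."""
        rows = [pd.DataFrame({"id": self.kept["id"], "kept": True,
                              "qc_reasons": ""})] if len(self.kept) else []
        if len(self.excluded):
            rows.append(pd.DataFrame({"id": self.excluded["id"], "kept": False,
                                      "qc_reasons": self.excluded["qc_reasons"]}))
        if not rows:
            return pd.DataFrame(columns=["id", "kept", "qc_reasons"])
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        lines = [f"records in: {self.n_input}",
                 f"kept: {len(self.kept)}",
                 f"excluded: {len(self.excluded)}"]
        for code in REASON_CODES:
            lines.append(f"  {code}: {self.counts.get(code, 0)}")
        for flag in self.flags:
            lines.append(f"flag: {flag}")
        return "\n".join(lines)


def apply_exclusions(records: pd.DataFrame, config: QcConfig | None = None) -> QcReport:
    """Apply the five exclusion rules and report per-record disposition.

    ``records`` must carry the canonical cohort columns ``id``, ``sex``,
    ``u24_vol_l``, ``u24_cr_mmol``, ``missed_l`` and ``spot_cr_mmol_l``.
    Deterministic for a fixed input order; an empty input yields an empty
    report.
    """
    config = config or QcConfig()
    reasons: dict[int, list[str]] = {}
    if len(records) == 0:
        return QcReport(kept=records.copy(), excluded=records.copy().assign(qc_reasons=""),
                        counts={c: 0 for c in REASON_CODES})

    vol = records["u24_vol_l"].to_numpy(float)
    missed = records["missed_l"].to_numpy(float) if "missed_l" in records else np.zeros(len(records))
    missed = np.nan_to_num(missed)
    cr24 = records["u24_cr_mmol"].to_numpy(float)
    spotcr = records["spot_cr_mmol_l"].to_numpy(float)
    is_male = records["sex"].astype(str).str.upper().str.startswith("M").to_numpy()

    # rule 1: missed volume > 20% of the total (collected + missed)
    frac = missed / (vol + missed)
    r1 = frac > config.missed_fraction_max
    # rule 2: collected volume below the floor
    r2 = vol < config.volume_min
    # rule 3: 24 h creatinine outside the sex-specific band (strict)
    lo = np.where(is_male, config.cr24_bounds_male[0], config.cr24_bounds_female[0])
    hi = np.where(is_male, config.cr24_bounds_male[1], config.cr24_bounds_female[1])
    r3 = (cr24 < lo) | (cr24 > hi)

    survivors13 = ~(r1 | r2 | r3)
    stats: dict = {}
    flags: list[str] = []
    if survivors13.sum() >= 3:
        m = config.sd_multiplier
        stats["u24_vol_l"] = (float(vol[survivors13].mean()),
                              float(vol[survivors13].std(ddof=1)))
        stats["spot_cr_mmol_l"] = (float(spotcr[survivors13].mean()),
                                   float(spotcr[survivors13].std(ddof=1)))
        r4 = np.abs(vol - stats["u24_vol_l"][0]) > m * stats["u24_vol_l"][1]
        r5 = np.abs(spotcr - stats["spot_cr_mmol_l"][0]) > m * stats["spot_cr_mmol_l"][1]
        # SD rules only judge records still in play after rules 1-3
        r4 &= survivors13
        r5 &= survivors13
    else:
        flags.append("sd_rules_skipped: fewer than 3 survivors of rules 1-3")
        r4 = np.zeros(len(records), bool)
        r5 = np.zeros(len(records), bool)

    rule_masks = dict(zip(REASON_CODES, [r1, r2, r3, r4, r5]))
    counts = {code: int(mask.sum()) for code, mask in rule_masks.items()}
    any_excl = r1 | r2 | r3 | r4 | r5

    reason_col = []
    for i in range(len(records)):
        reason_col.append(";".join(code for code in REASON_CODES if rule_masks[code][i]))
    reason_series = pd.Series(reason_col, index=records.index)

    excluded = records.loc[any_excl].copy()
    excluded["qc_reasons"] = reason_series[any_excl]
    kept = records.loc[~any_excl].copy()
    return QcReport(kept=kept, excluded=excluded, counts=counts,
                    stats=stats, flags=flags)


def flowchart_counts(report: QcReport, initial_n: int | None = None) -> dict:
    """Enrollment-flowchart retention summary.

    Returns excluded count, kept count and kept percentage (one decimal
    place) relative to ``initial_n`` (defaults to the report's input size;
    may be larger when upstream enrollment exclusions preceded the urine
    QC).  ``initial_n`` smaller than the kept count is an inconsistency.
    """
    kept = len(report.kept)
    if initial_n is None:
        initial_n = report.n_input
    if initial_n < kept:
        raise ValueError(f"initial_n {initial_n} < kept {kept}")
    excluded = initial_n - kept
    pct = round(100.0 * kept / initial_n, 1) if initial_n else 0.0
    return {"initial": int(initial_n), "excluded": int(excluded),
            "kept": int(kept), "kept_pct": pct}
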