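"""Formula arithmetic against hand-computed oracles, unit conversions,
scaling laws, and the per-record / batch dispatch."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spoturine import estimators as est
from spoturine.estimators import (
    COEFFICIENTS, EstimatorId, ParticipantRecord, Sex, SpotSpecimen,
    cr_mmol_to_mg, estimate_all, estimate_batch, estimate_k_new,
    estimate_kawasaki, estimate_na_intersalt, estimate_na_new,
    estimate_tanaka, na_mmol_to_g_salt, predict_creatinine_kawasaki,
    predict_creatinine_tanaka,
)

SPOT = SpotSpecimen(na=130.0, k=55.0, cr=8.9)


# --------------------------------------------------------------------------
# unit conversions
# --------------------------------------------------------------------------

@pytest.mark.parametrize("cr,expected", [(0.0, 0.0), (1.0, 113.12),
                                         (8.93, 1010.1616)])
def test_creatinine_unit_conversion(cr, expected):
    assert cr_mmol_to_mg(cr) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("na,expected_2dp", [(12.30, 0.72), (0.0, 0.0),
                                             (17.1, 1.00)])
def test_sodium_to_salt_grams(na, expected_2dp):
    assert round(na_mmol_to_g_salt(na), 2) == expected_2dp


@pytest.mark.parametrize("fn", [cr_mmol_to_mg, na_mmol_to_g_salt])
def test_conversions_reject_negative(fn):
    with pytest.raises(ValueError):
        fn(-1.0)


@given(st.floats(min_value=1e-6, max_value=1e4))
def test_creatinine_conversion_round_trip(cr):
    assert cr_mmol_to_mg(cr) / 113.12 == pytest.approx(cr, rel=1e-12)


# --------------------------------------------------------------------------
# the new formulas (hand-evaluated linear predictors)
# --------------------------------------------------------------------------

@pytest.mark.parametrize("sex,expected", [
    (Sex.MALE, 193.0462), (Sex.FEMALE, 164.1920)])
def test_new_sodium_formula_hand_values(sex, expected):
    assert estimate_na_new(sex, 65, 25, SPOT) == pytest.approx(expected, abs=1e-3)


def test_new_sodium_intercept_limit():
    # all covariates zero with the ratio term vanishing -> intercept
    out = estimate_na_new(Sex.MALE, 0, 0, spot_na=0.0, spot_cr=1.0)
    assert out == pytest.approx(41.492)


@pytest.mark.parametrize("sex,expected", [
    (Sex.MALE, 52.6292), (Sex.FEMALE, 39.9197)])
def test_new_potassium_formula_hand_values(sex, expected):
    assert estimate_k_new(sex, 65, 25, SPOT) == pytest.approx(expected, abs=1e-3)


def test_new_potassium_log_terms_vanish():
    # k/cr = na/cr = 1 kills both log terms
    out = estimate_k_new(Sex.MALE, 65, 25, spot_k=55, spot_na=55, spot_cr=55)
    assert out == pytest.approx(-0.052 * 65 + 0.410 * 25 + 0.031 * 55 - 1.035)


def test_new_potassium_requires_positive_concentrations():
    with pytest.raises(ValueError):
        estimate_k_new(Sex.MALE, 65, 25, spot_k=0.0, spot_na=130, spot_cr=8.9)
    with pytest.raises(ValueError):
        estimate_na_new(Sex.MALE, 65, 25, spot_na=130, spot_cr=0.0)


# --------------------------------------------------------------------------
# published comparators
# --------------------------------------------------------------------------

@pytest.mark.parametrize("sex,expected", [
    (Sex.MALE, 1376.9), (Sex.FEMALE, 1059.15)])
def test_kawasaki_creatinine_prediction(sex, expected):
    assert predict_creatinine_kawasaki(sex, 70, 165, 65) == pytest.approx(
        expected, abs=1e-6)


def test_kawasaki_creatinine_out_of_domain():
    # intercept-only limit is negative -> domain error
    with pytest.raises(ValueError):
        predict_creatinine_kawasaki(Sex.MALE, 0.0, 0.0, 0.0)


@pytest.mark.parametrize("w,h,a,expected", [
    (70, 165, 65, 1328.35), (60, 150, 80, 906.75)])
def test_tanaka_creatinine_prediction(w, h, a, expected):
    assert predict_creatinine_tanaka(w, h, a) == pytest.approx(expected, abs=1e-6)


def test_tanaka_creatinine_out_of_domain():
    with pytest.raises(ValueError):
        predict_creatinine_tanaka(0.0, 0.0, 0.0)


@pytest.mark.parametrize("analyte,expected", [("na", 217.343), ("k", 62.445)])
def test_kawasaki_estimates_hand_values(analyte, expected):
    out = estimate_kawasaki(Sex.MALE, 70, 165, 65, SPOT, analyte)
    assert out == pytest.approx(expected, abs=1e-2)


@pytest.mark.parametrize("analyte,expected", [("na", 165.152), ("k", 48.109)])
def test_tanaka_estimates_hand_values(analyte, expected):
    assert estimate_tanaka(70, 165, 65, SPOT, analyte) == pytest.approx(
        expected, abs=1e-2)


@pytest.mark.parametrize("fn,args", [
    (estimate_kawasaki, (Sex.MALE, 70, 165, 65)),
    (estimate_tanaka, (70, 165, 65))])
def test_ratio_power_estimates_vanish_at_zero_analyte(fn, args):
    assert fn(*args, analyte="na", spot_conc=0.0, spot_cr=8.9) == 0.0


@pytest.mark.parametrize("sex,expected", [
    (Sex.MALE, 173.035), (Sex.FEMALE, 110.846)])
def test_intersalt_hand_values(sex, expected):
    assert estimate_na_intersalt(sex, 65, 25, SPOT) == pytest.approx(
        expected, abs=1e-3)


def test_intersalt_intercept_limit():
    assert estimate_na_intersalt(Sex.MALE, 0, 0, spot_na=0, spot_k=0,
                                 spot_cr=0) == pytest.approx(25.46)


# --------------------------------------------------------------------------
# invariants: scaling, monotonicity, sex dispatch, registry transcription
# --------------------------------------------------------------------------

def test_kawasaki_sqrt_scaling_law():
    base = estimate_kawasaki(Sex.MALE, 70, 165, 65, analyte="na",
                             spot_conc=130.0, spot_cr=8.9)
    doubled = estimate_kawasaki(Sex.MALE, 70, 165, 65, analyte="na",
                                spot_conc=260.0, spot_cr=8.9)
    assert doubled == pytest.approx(math.sqrt(2) * base, rel=1e-9)


def test_tanaka_power_scaling_law():
    base = estimate_tanaka(70, 165, 65, analyte="na", spot_conc=130.0,
                           spot_cr=8.9)
    doubled = estimate_tanaka(70, 165, 65, analyte="na", spot_conc=260.0,
                              spot_cr=8.9)
    assert doubled == pytest.approx(2 ** 0.392 * base, rel=1e-9)


@given(na=st.floats(min_value=1.0, max_value=400.0),
       bump=st.floats(min_value=0.1, max_value=50.0))
def test_sodium_estimates_increase_in_spot_sodium(na, bump):
    for fn in (
        lambda v: estimate_na_new(Sex.FEMALE, 65, 25, spot_na=v, spot_cr=8.9),
        lambda v: estimate_na_intersalt(Sex.MALE, 65, 25, spot_na=v,
                                        spot_k=55, spot_cr=8.9),
        lambda v: estimate_kawasaki(Sex.MALE, 70, 165, 65, analyte="na",
                                    spot_conc=v, spot_cr=8.9),
        lambda v: estimate_tanaka(70, 165, 65, analyte="na", spot_conc=v,
                                  spot_cr=8.9),
    ):
        assert fn(na + bump) > fn(na)


@given(na=st.floats(min_value=1.0, max_value=400.0),
       bump=st.floats(min_value=0.1, max_value=50.0))
def test_new_potassium_decreases_in_spot_sodium(na, bump):
    lo = estimate_k_new(Sex.MALE, 65, 25, spot_k=55, spot_na=na, spot_cr=8.9)
    hi = estimate_k_new(Sex.MALE, 65, 25, spot_k=55, spot_na=na + bump,
                        spot_cr=8.9)
    assert hi < lo


def test_sex_dispatch_differs_where_expected():
    args = (65, 25, SPOT)
    assert estimate_na_new(Sex.MALE, *args) != estimate_na_new(Sex.FEMALE, *args)
    assert estimate_k_new(Sex.MALE, *args) != estimate_k_new(Sex.FEMALE, *args)
    assert estimate_na_intersalt(Sex.MALE, *args) != estimate_na_intersalt(
        Sex.FEMALE, *args)
    assert (estimate_kawasaki(Sex.MALE, 70, 165, 65, SPOT, "na")
            != estimate_kawasaki(Sex.FEMALE, 70, 165, 65, SPOT, "na"))
    # Tanaka has no sex branch at all: same inputs, same output by identity
    assert estimate_tanaka(70, 165, 65, SPOT, "na") == estimate_tanaka(
        70, 165, 65, SPOT, "na")


# independently keyed transcription of the published coefficient tables,
# deliberately written out again rather than imported
_EXPECTED = {
    ("new", "na", "M"): [41.492, -0.191, 4.349, 0.229, 1.744],
    ("new", "na", "F"): [147.159, -1.030, 2.011, 0.143, 1.035],
    ("new", "k", "M"): [-1.035, -0.052, 0.410, 0.031, 33.280, -5.789],
    ("new", "k", "F"): [4.318, -0.235, 0.530, 0.040, 30.990, -7.837],
    ("kawasaki", "prucr", "M"): [15.12, 7.39, -12.63, -79.90],
    ("kawasaki", "prucr", "F"): [8.58, 5.09, -4.72, -74.50],
    ("kawasaki", "const", ""): [16.30, 7.20, 0.5],
    ("tanaka", "prucr", ""): [14.89, 16.14, -2.04, -2244.45],
    ("tanaka", "const", ""): [21.98, 0.392, 7.59, 0.431],
    ("intersalt", "na", "M"): [25.46, 0.46, -2.75, -0.13, 4.10, 0.26, 0.0],
    ("intersalt", "na", "F"): [5.07, 0.34, -2.16, -0.09, 2.39, 2.35, -0.03],
}


def test_registry_matches_independent_transcription():
    C = COEFFICIENTS
    for sex, tag in ((Sex.MALE, "M"), (Sex.FEMALE, "F")):
        c = C["new"]["na"][sex]
        assert [c["intercept"], c["age"], c["bmi"], c["spot_na"],
                c["na_cr_ratio"]] == _EXPECTED[("new", "na", tag)]
        c = C["new"]["k"][sex]
        assert [c["intercept"], c["age"], c["bmi"], c["spot_k"],
                c["ln_k_cr"], c["ln_na_cr"]] == _EXPECTED[("new", "k", tag)]
        c = C["kawasaki"]["prucr"][sex]
        assert [c["weight"], c["height"], c["age"],
                c["intercept"]] == _EXPECTED[("kawasaki", "prucr", tag)]
        c = C["intersalt"]["na"][sex]
        assert [c["intercept"], c["spot_na"], c["spot_cr"], c["spot_k"],
                c["bmi"], c["age"], c["age2"]] == _EXPECTED[("intersalt", "na", tag)]
    assert [C["kawasaki"]["na"]["const"], C["kawasaki"]["k"]["const"],
            C["kawasaki"]["na"]["exponent"]] == _EXPECTED[("kawasaki", "const", "")]
    c = C["tanaka"]["prucr"]
    assert [c["weight"], c["height"], c["age"],
            c["intercept"]] == _EXPECTED[("tanaka", "prucr", "")]
    assert [C["tanaka"]["na"]["const"], C["tanaka"]["na"]["exponent"],
            C["tanaka"]["k"]["const"],
            C["tanaka"]["k"]["exponent"]] == _EXPECTED[("tanaka", "const", "")]


# --------------------------------------------------------------------------
# records and dispatch
# --------------------------------------------------------------------------

def test_participant_record_derives_and_checks_bmi():
    r = ParticipantRecord(id="x", sex=Sex.MALE, age=65, height=170, weight=72)
    assert r.bmi == pytest.approx(72 / 1.70 ** 2)
    with pytest.raises(ValueError):
        ParticipantRecord(id="x", sex=Sex.MALE, age=65, bmi=30.0,
                          height=170, weight=72)


def test_estimate_all_full_record():
    r = ParticipantRecord(id="x", sex=Sex.MALE, age=65, bmi=25.0,
                          height=165, weight=68.1)
    results = {res.method: res for res in estimate_all(r, SPOT)}
    assert len(results) == 4
    assert results[EstimatorId.INTERSALT].est_k is None
    assert any("INTERSALT" in reason
               for reason in results[EstimatorId.INTERSALT].missing)
    assert results[EstimatorId.KAWASAKI].prucr24h is not None
    assert results[EstimatorId.NEW].est_na == pytest.approx(193.046, abs=1e-3)


def test_estimate_all_without_anthropometry():
    r = ParticipantRecord(id="x", sex=Sex.FEMALE, age=65, bmi=25.0)
    results = {res.method: res for res in estimate_all(r, SPOT)}
    for m in (EstimatorId.KAWASAKI, EstimatorId.TANAKA):
        assert results[m].est_na is None
        assert results[m].missing  # reason given, not silently dropped
    assert results[EstimatorId.NEW].est_na is not None
    assert results[EstimatorId.INTERSALT].est_na is not None


def test_negative_estimate_flagged_not_clipped():
    # extreme age drives the female sodium formula negative
    r = ParticipantRecord(id="x", sex=Sex.FEMALE, age=300, bmi=16.0)
    spot = SpotSpecimen(na=5.0, k=5.0, cr=10.0)
    res = {x.method: x for x in estimate_all(r, spot)}[EstimatorId.NEW]
    assert res.est_na < 0
    assert any("negative" in w for w in res.warnings)


def test_batch_matches_scalar_dispatch(tiny_cohort):
    out = estimate_batch(tiny_cohort)
    i = 2  # male, age 65, bmi 25, na 130, k 55, cr 9
    row = out.iloc[i]
    assert row["est_na_new"] == pytest.approx(
        estimate_na_new(Sex.MALE, row["age_y"], row["bmi"],
                        spot_na=row["spot_na_mmol_l"],
                        spot_cr=row["spot_cr_mmol_l"]))
    assert row["est_k_tanaka"] == pytest.approx(
        estimate_tanaka(row["weight_kg"], row["height_cm"], row["age_y"],
                        analyte="k", spot_conc=row["spot_k_mmol_l"],
                        spot_cr=row["spot_cr_mmol_l"]))
    assert row["est_na_intersalt"] == pytest.approx(
        estimate_na_intersalt(Sex.MALE, row["age_y"], row["bmi"],
                              spot_na=row["spot_na_mmol_l"],
                              spot_k=row["spot_k_mmol_l"],
                              spot_cr=row["spot_cr_mmol_l"]))


def test_batch_missing_anthropometry_gives_nan(tiny_cohort):
    df = tiny_cohort.copy()
    df.loc[df.index[0], "height_cm"] = np.nan
    out = estimate_batch(df)
    assert np.isnan(out.loc[out.index[0], "est_na_kawasaki"])
    assert not np.isnan(out.loc[out.index[0], "est_na_new"])


def test_cohort_csv_round_trip(tmp_path, tiny_cohort):
    path = tmp_path / "cohort.csv"
    est.write_cohort(tiny_cohort, path)
    back = est.read_cohort(path)
    pd.testing.assert_frame_equal(back, tiny_cohort, check_exact=False)


def test_read_cohort_rejects_bad_schema(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"id": [1], "sex": ["M"]}).to_csv(path, index=False)
    with pytest.raises(ValueError, match="missing required columns"):
        est.read_cohort(path)
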