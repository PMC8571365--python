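"""Feature construction, probit arithmetic, prediction and fitting."""

import dataclasses
import random

import numpy as np
import pytest
from scipy.stats import norm

from trimp.model import (
    COEFFICIENT_NAMES,
    FEATURE_NAMES,
    CoefficientTable,
    MissingCodeError,
    ModelFitError,
    TRIMPFeatures,
    build_features,
    fit_trimp,
    linear_predictor,
    predict,
    published_coefficients,
)
from trimp.wmdp import pmr
from conftest import make_patient


def zero_features(**overrides):
    base = dict(patient_id="x", wmdp1=0.0, wmdp2=0.0, wmdp3=0.0, wmdp4=0.0,
                wmdp5=0.0, interaction=0.0, same_region=0, nbr=0, nbr_fp=0.0,
                age=0.0, male=0, cci=0, mechanism=0, gcs=0, icu=0, vent=0,
                sbp_code=0, pulse_code=0, rr_code=0)
    base.update(overrides)
    return TRIMPFeatures(**base)


TABLE = {"450203": 0.4, "140216": 0.9, "410201": 0.7, "730204": 0.01,
         "540000": 0.2, "460000": 0.35}


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def test_fewer_than_five_injuries_zero_padded():
    p = make_patient("p1", injuries=(("450203", 3), ("140216", 5)))
    f = build_features(p, TABLE)
    assert (f.wmdp1, f.wmdp2) == (0.9, 0.4)
    assert (f.wmdp3, f.wmdp4, f.wmdp5) == (0.0, 0.0, 0.0)
    assert f.interaction == pytest.approx(0.9 * 0.4)


def test_same_region_flag_for_two_thorax_injuries():
    p = make_patient("p1", injuries=(("450203", 3), ("410201", 4)))
    assert build_features(p, TABLE).same_region == 1
    q = make_patient("p1", injuries=(("450203", 3), ("140216", 5)))
    assert build_features(q, TABLE).same_region == 0


def test_single_region_nbr_fractional_power():
    p = make_patient("p1", injuries=(("450203", 3),))
    f = build_features(p, TABLE)
    assert f.nbr == 1 and f.nbr_fp == pytest.approx(1.0)
    q = make_patient("p1", injuries=(("450203", 3), ("140216", 5), ("730204", 1)))
    g = build_features(q, TABLE)
    assert g.nbr == 3 and g.nbr_fp == pytest.approx(3 ** 0.382)


def test_missing_code_error_and_pmr_fallback():
    p = make_patient("p1", age=0, injuries=(("999999", 3),))
    with pytest.raises(MissingCodeError, match="999999"):
        build_features(p, TABLE)
    f = build_features(p, TABLE, on_missing="pmr")
    assert f.wmdp1 == pytest.approx(pmr(0))


def test_wmdp_ties_broken_by_severity_then_predot():
    table = {"450203": 0.5, "140216": 0.5}
    p = make_patient("p1", injuries=(("450203", 3), ("140216", 5)))
    f = build_features(p, table)
    # equal scores: the severity-5 head injury ranks first
    assert f.same_region == 0
    q = make_patient("p1", injuries=(("450203", 3), ("140216", 3)))
    # severity tied too: lexicographic predot -> head injury first again
    assert build_features(q, table).wmdp1 == 0.5


def test_appending_zero_score_injury_leaves_features_unchanged():
    table = dict(TABLE, **{"920000": 0.0})
    injuries = (("450203", 3), ("140216", 5), ("410201", 2), ("540000", 2),
                ("730204", 1))
    p = make_patient("p1", injuries=injuries)
    q = make_patient("p1", injuries=injuries + (("920000", 1),))
    f, g = build_features(p, table), build_features(q, table)
    for name in FEATURE_NAMES:
        if name in ("nbr", "nbr_fp"):  # the extra injury adds a body region
            continue
        assert getattr(f, name) == getattr(g, name)
    assert (f.wmdp1, f.wmdp2, f.wmdp3, f.wmdp4, f.wmdp5) == \
        (g.wmdp1, g.wmdp2, g.wmdp3, g.wmdp4, g.wmdp5)


def test_feature_invariants_enforced():
    with pytest.raises(ValueError):
        zero_features(wmdp1=0.1, wmdp2=0.5)  # not descending
    with pytest.raises(ValueError):
        zero_features(wmdp1=0.5, wmdp2=0.5, interaction=0.1)
    with pytest.raises(ValueError):
        zero_features(same_region=2)


# ---------------------------------------------------------------------------
# Linear predictor and published coefficients
# ---------------------------------------------------------------------------


def test_intercept_at_zero_vector():
    eta = linear_predictor(zero_features(), published_coefficients())
    assert eta == pytest.approx(-7.87668, abs=1e-12)


def test_unit_wmdp1_effect():
    coefs = published_coefficients()
    eta = linear_predictor(zero_features(wmdp1=1.0), coefs)
    assert eta == pytest.approx(-7.87668 + 1.74286, abs=1e-12)


def test_unit_gcs_effect():
    coefs = published_coefficients()
    d = (linear_predictor(zero_features(gcs=9), coefs)
         - linear_predictor(zero_features(gcs=8), coefs))
    assert d == pytest.approx(-0.11159, abs=1e-12)


def test_published_table_spot_values():
    c = published_coefficients()
    assert c["wmdp1"] == 1.74286
    assert c["vent"] == 1.76084
    assert c["cci"] == 0.29517
    assert c.se("age") == 0.00102
    assert c.n_fit == 199840


def test_linear_predictor_matches_term_sum_oracle():
    rng = random.Random(11)
    coefs = published_coefficients()
    for _ in range(50):
        w = sorted((rng.random() for _ in range(5)), reverse=True)
        f = zero_features(
            wmdp1=w[0], wmdp2=w[1], wmdp3=w[2], wmdp4=w[3], wmdp5=w[4],
            interaction=w[0] * w[1], same_region=rng.randint(0, 1),
            nbr=(nbr := rng.randint(1, 6)), nbr_fp=nbr ** 0.382,
            age=rng.uniform(1, 89), male=rng.randint(0, 1),
            cci=rng.randint(0, 6), mechanism=rng.randint(1, 6),
            gcs=rng.randint(3, 15), icu=rng.randint(0, 1),
            vent=rng.randint(0, 1), sbp_code=rng.randint(0, 4),
            pulse_code=rng.randint(0, 4), rr_code=rng.randint(0, 4))
        oracle = coefs.estimates[0]
        for name, c in zip(FEATURE_NAMES, coefs.estimates[1:]):
            oracle += c * getattr(f, name)
        assert linear_predictor(f, coefs) == pytest.approx(oracle, abs=1e-12)


def test_coefficient_table_round_trip(tmp_path):
    coefs = published_coefficients()
    coefs.to_json(tmp_path / "c.json")
    assert CoefficientTable.from_json(tmp_path / "c.json").estimates == \
        coefs.estimates


def test_coefficient_table_requires_all_names():
    with pytest.raises(ValueError, match="missing"):
        CoefficientTable.from_mapping(
            {"constant": {"estimate": 0, "robust_se": 1}}, n_fit=1)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def test_pdeath_is_normal_cdf_of_eta(sim_cohort, catalog):
    preds = predict(sim_cohort[:50], catalog.lethality_map())
    for r in preds:
        assert r.p_death == pytest.approx(norm.cdf(r.eta))
        assert r.p_survival == pytest.approx(1 - r.p_death)
    assert [r.patient_id for r in preds] == \
        [p.patient_id for p in sim_cohort[:50]]


def test_ventilated_twin_has_higher_risk():
    base = dict(injuries=(("450203", 3), ("140216", 5)), age=50)
    p = make_patient("p1", **base)
    q = make_patient("p2", vent_days=2.0, **base)
    rp, rq = predict([p, q], TABLE)
    assert rq.p_death > rp.p_death


def test_monotone_in_positive_coefficient_features():
    coefs = published_coefficients()
    base = zero_features(gcs=15, nbr=1, nbr_fp=1.0, mechanism=3, age=40.0)
    for name in ("age", "cci", "vent", "icu"):
        lo = linear_predictor(base, coefs)
        hi = linear_predictor(dataclasses.replace(base, **{name: 41 if name == "age" else 1}), coefs)
        assert hi > lo, name
    # raising each lower wmdp slot (keeping the vector descending) adds risk
    filled = zero_features(wmdp1=1.0, wmdp2=1.0, interaction=1.0,
                           gcs=15, nbr=1, nbr_fp=1.0, mechanism=3, age=40.0)
    for name in ("wmdp3", "wmdp4", "wmdp5"):
        hi = dataclasses.replace(filled, **{name: 1.0})
        assert linear_predictor(hi, coefs) > linear_predictor(filled, coefs), name
        filled = hi


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _random_features(n, seed, constant_col=None):
    rng = random.Random(seed)
    out = []
    for i in range(n):
        w = sorted((rng.random() for _ in range(5)), reverse=True)
        nbr = rng.randint(1, 6)
        kw = dict(
            patient_id=f"p{i}", wmdp1=w[0], wmdp2=w[1], wmdp3=w[2], wmdp4=w[3],
            wmdp5=w[4], interaction=w[0] * w[1], same_region=rng.randint(0, 1),
            nbr=nbr, nbr_fp=nbr ** 0.382, age=rng.uniform(1, 89),
            male=rng.randint(0, 1), cci=rng.randint(0, 3),
            mechanism=rng.randint(1, 6), gcs=rng.randint(3, 15),
            icu=rng.randint(0, 1), vent=rng.randint(0, 1),
            sbp_code=rng.randint(0, 4), pulse_code=rng.randint(0, 4),
            rr_code=rng.randint(0, 4))
        if constant_col:
            kw[constant_col] = 1
        out.append(TRIMPFeatures(**kw))
    return out


def test_all_survivors_is_a_separation_error():
    feats = _random_features(200, seed=1)
    with pytest.raises(ModelFitError, match="events"):
        fit_trimp(feats, [0] * 200)


def test_constant_column_is_a_rank_deficiency_error():
    feats = _random_features(300, seed=2, constant_col="vent")
    y = [i % 2 for i in range(300)]
    with pytest.raises(ModelFitError, match="vent"):
        fit_trimp(feats, y)


def test_fit_recovers_wmdp1_on_simulated_data(catalog, sim_cohort):
    from trimp.synthetic import SimulationConfig, known_truth

    truth, coefs = known_truth(catalog, SimulationConfig(n_patients=6000, seed=11))
    feats = [build_features(p, truth) for p in sim_cohort]
    fit = fit_trimp(feats, [p.died for p in sim_cohort])
    assert fit.n_fit == len(sim_cohort)
    assert fit.log_likelihood < 0
    i = COEFFICIENT_NAMES.index("age")
    assert abs(fit.estimates[i] - coefs.estimates[i]) < 4 * fit.robust_se[i]
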