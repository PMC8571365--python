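"""Registry I/O, coding tables, the exclusion cascade, and splitting."""

import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trimp.cohort import (
    CohortValidationError,
    ExclusionConfig,
    InjuryRecord,
    NontraumaticMechanismError,
    VitalCodingConfig,
    VitalCodingConfigError,
    ais_to_iss_region,
    apply_exclusions,
    charlson_index,
    code_vitals,
    map_mechanism,
    read_cohort,
    split_cohort,
    write_cohort,
)
from conftest import make_patient


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_cohort_roundtrip_identity(tmp_path):
    cohort = [
        make_patient("a1", injuries=(("450203", 3), ("140216", 5)),
                     dx_codes=["410.1"], cci=None),
        make_patient("a2", age=77, gender="female", outcome="died",
                     vent_days=4.0, icu_days=6.0, injuries=(("730204", 1),)),
    ]
    write_cohort(cohort, tmp_path / "patients.csv", tmp_path / "injuries.csv")
    back = read_cohort(tmp_path / "patients.csv", tmp_path / "injuries.csv")
    assert sorted(p.patient_id for p in back) == ["a1", "a2"]
    by_id = {p.patient_id: p for p in back}
    assert by_id["a1"] == cohort[0]
    assert by_id["a2"] == cohort[1]
    assert len(by_id["a1"].injuries) == 2


def test_invalid_severity_reported_with_line_number(tmp_path):
    cohort = [make_patient("a1")]
    write_cohort(cohort, tmp_path / "patients.csv", tmp_path / "injuries.csv")
    with open(tmp_path / "injuries.csv", "a", newline="") as fh:
        csv.writer(fh).writerow(["a1", "450203", 7])
    with pytest.raises(CohortValidationError, match="injuries.csv:3"):
        read_cohort(tmp_path / "patients.csv", tmp_path / "injuries.csv")


def test_orphan_injury_is_an_error(tmp_path):
    write_cohort([make_patient("a1")], tmp_path / "p.csv", tmp_path / "i.csv")
    with open(tmp_path / "i.csv", "a", newline="") as fh:
        csv.writer(fh).writerow(["ghost", "450203", 3])
    with pytest.raises(CohortValidationError, match="orphan"):
        read_cohort(tmp_path / "p.csv", tmp_path / "i.csv")


def test_injury_record_invariants():
    with pytest.raises(ValueError):
        InjuryRecord("p", "45020", 3)  # five digits
    with pytest.raises(ValueError):
        InjuryRecord("p", "050203", 3)  # leading zero
    with pytest.raises(ValueError):
        InjuryRecord("p", "450203", 7)  # invalid severity


# ---------------------------------------------------------------------------
# Mechanism coding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ecode, family", [
    ("E920.3", 1),   # cut/pierce -> stab
    ("E960.0", 2),   # unarmed fight -> violence
    ("E916", 3),     # struck by falling object -> blunt
    ("E885.9", 4),   # fall on same level -> fall
    ("E819.0", 5),   # motor vehicle traffic -> motor vehicle crash
    ("E922.0", 6),   # handgun -> firearm
    ("E9550", 6),    # dotless registry form, firearm (self-inflicted)
])
def test_mechanism_families(ecode, family):
    assert map_mechanism(ecode) == family


@pytest.mark.parametrize("ecode", ["E860.0", "E890", "E910", "E912", "E927"])
def test_nontraumatic_mechanisms_signal_exclusion(ecode):
    with pytest.raises(NontraumaticMechanismError):
        map_mechanism(ecode)


def test_malformed_ecode_is_a_value_error():
    with pytest.raises(ValueError):
        map_mechanism("notacode")


def test_mechanism_range_always_one_to_six():
    # scan every three-digit E-code family; mapped values stay in 1-6
    for whole in range(800, 1000):
        try:
            fam = map_mechanism(f"E{whole}")
        except NontraumaticMechanismError:
            continue
        assert fam in range(1, 7)


# ---------------------------------------------------------------------------
# Body regions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("predot, region", [
    ("450203", 3),   # rib fracture -> thorax
    ("140216", 1),   # brainstem -> head/neck
    ("730204", 5),   # digital nerve -> limbs
    ("310000", 1),   # neck chapter -> head/neck
    ("210000", 2),   # face
    ("540000", 4),   # abdomen
    ("853000", 5),   # lower extremity
    ("910000", 6),   # external
    ("640278", 1),   # cervical spine (level digit 2)
    ("640462", 3),   # thoracic spine (level digit 4)
    ("650600", 4),   # lumbar spine (level digit 6)
])
def test_ais_chapter_to_iss_region(predot, region):
    assert ais_to_iss_region(predot) == region


def test_every_chapter_maps_into_six_regions():
    regions = {ais_to_iss_region(f"{c}10210") for c in "123456789"}
    assert regions <= set(range(1, 7))


def test_invalid_predot_rejected():
    with pytest.raises(ValueError):
        ais_to_iss_region("45020")


# ---------------------------------------------------------------------------
# Charlson index
# ---------------------------------------------------------------------------


def test_charlson_weights_and_hierarchies():
    assert charlson_index([]) == 0
    assert charlson_index(["410.1"]) == 1          # myocardial infarction
    assert charlson_index(["197.0"]) == 6          # metastatic solid tumour
    # hierarchy: metastasis supersedes the primary malignancy
    assert charlson_index(["197.0", "153.4"]) == 6
    # complicated diabetes supersedes uncomplicated
    assert charlson_index(["250.1", "250.5"]) == 2
    # unrecognized codes contribute nothing
    assert charlson_index(["V99.9", "799.9"]) == 0


def test_charlson_invariant_to_order_and_duplication():
    codes = ["410.1", "428.0", "042"]
    expected = charlson_index(codes)
    assert charlson_index(codes[::-1]) == expected
    assert charlson_index(codes * 3) == expected
    assert charlson_index(["410.1", "412"]) == 1  # same condition twice


# ---------------------------------------------------------------------------
# Vital-sign coding
# ---------------------------------------------------------------------------


def test_normal_vitals_code_to_zero():
    assert code_vitals(120, 75, 16) == (0, 0, 0)


def test_zero_sbp_is_maximal_derangement():
    sbp_code, _, _ = code_vitals(0, 75, 16)
    cfg = VitalCodingConfig.default()
    assert sbp_code == max(code for _, _, code in cfg.sbp)


def test_sbp_codes_non_increasing_with_pressure():
    codes = [code_vitals(s, 75, 16)[0] for s in range(0, 201)]
    assert all(a >= b for a, b in zip(codes, codes[1:]))


@pytest.mark.parametrize("bad_table", [
    ((0, 60, 1), (50, None, 0)),            # overlap
    ((0, 60, 0), (61, 100, 2), (101, None, 1)),  # non-monotone away from 0
    ((0, 60, 1), (61, 100, 2)),             # no normal band, bounded end
])
def test_bad_coding_config_rejected(bad_table):
    with pytest.raises(VitalCodingConfigError):
        VitalCodingConfig(sbp=bad_table,
                          pulse=((0, None, 0),), rr=((0, None, 0),))


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------


def _fixture_cohort():
    good = [make_patient(f"g{i}") for i in range(7)]
    burn = make_patient("burn", ecode="E890")
    old = make_patient("old", age=95)
    ed = make_patient("ed", ed_only=True)
    return good + [burn, old, ed]


def test_exclusion_cascade_counts_and_ledger():
    cohort = _fixture_cohort()
    kept, ledger = apply_exclusions(cohort, ExclusionConfig(min_hospital_volume=1))
    assert ledger.n_input == 10 and ledger.n_output == 7
    nonzero = {name: n for name, n in ledger.steps if n}
    assert nonzero == {"nontraumatic_mechanism": 1, "age_over_max": 1,
                       "ed_only": 1}
    assert ledger.n_input == ledger.n_output + sum(n for _, n in ledger.steps)


def test_exclusions_idempotent_on_clean_cohort():
    cohort = [make_patient(f"g{i}") for i in range(5)]
    kept, ledger = apply_exclusions(cohort, ExclusionConfig(min_hospital_volume=1))
    assert kept == cohort
    assert all(n == 0 for _, n in ledger.steps)


def test_severity_nine_only_patient_excluded():
    p = make_patient("s9", injuries=(("450203", 9), ("140216", 9)))
    kept, ledger = apply_exclusions([p], ExclusionConfig(min_hospital_volume=1))
    assert kept == []
    assert dict(ledger.steps)["severity_9_only"] == 1


def test_low_volume_hospital_rule():
    cohort = [make_patient(f"p{i}", hospital_id="small") for i in range(3)]
    kept, ledger = apply_exclusions(cohort, ExclusionConfig(min_hospital_volume=5))
    assert kept == [] and dict(ledger.steps)["low_volume_hospital"] == 3


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def test_split_exact_multiples():
    cohort = [make_patient(f"p{i}") for i in range(600)]
    s = split_cohort(cohort, (2 / 3, 1 / 6, 1 / 6), seed=4)
    assert (len(s.derivation), len(s.fitting), len(s.validation)) == (400, 100, 100)


def test_split_deterministic_under_seed():
    cohort = [make_patient(f"p{i}") for i in range(101)]
    assert split_cohort(cohort, seed=9) == split_cohort(cohort, seed=9)
    assert split_cohort(cohort, seed=9) != split_cohort(cohort, seed=10)


@settings(deadline=None, max_examples=40)
@given(n=st.integers(min_value=3, max_value=200), seed=st.integers(0, 2 ** 16))
def test_split_partitions_disjoint_and_exhaustive(n, seed):
    cohort = [make_patient(f"p{i}") for i in range(n)]
    s = split_cohort(cohort, (0.666, 0.167, 0.167), seed=seed)
    union = s.derivation | s.fitting | s.validation
    assert union == {p.patient_id for p in cohort}
    assert len(s.derivation) + len(s.fitting) + len(s.validation) == n
    for size, frac in zip((len(s.derivation), len(s.fitting), len(s.validation)),
                          (0.666, 0.167, 0.167)):
        assert abs(size - n * frac) <= 1


def test_split_empty_cohort_rejected():
    with pytest.raises(ValueError):
        split_cohort([], seed=0)
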