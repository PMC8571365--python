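"""Trauma-registry data model, I/O, validation, exclusion cascade and splitting.

A cohort is a list of :class:`PatientRecord`, each carrying demographics,
physiology at presentation, the external-cause mechanism, comorbidity burden,
outcome, and one or more :class:`InjuryRecord` entries coded as AIS 2005
six-digit "predot" codes plus a post-dot severity digit.

The registry dialect is two delimited text files:

``patients.csv``
    one row per admission with columns ``patient_id, age, gender, ecode,
    mechanism, gcs, sbp, pulse, rr, icu_days, vent_days, los_days, cci,
    dx_codes, outcome, hospital_id, transfer_flag, dead_on_arrival_flag,
    ed_only_flag`` (``dx_codes`` is a ``;``-separated list; ``ecode`` or
    ``mechanism`` may be empty but not both, likewise ``cci``/``dx_codes``).

``injuries.csv``
    one row per injury with columns ``patient_id, predot, severity``.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("trimp")

VALID_SEVERITIES = frozenset({1, 2, 3, 4, 5, 6, 9})

#: ISS body regions.
REGION_HEAD_NECK = 1
REGION_FACE = 2
REGION_THORAX = 3
REGION_ABDOMEN = 4
REGION_LIMBS = 5
REGION_EXTERNAL = 6

REGION_NAMES = {
    1: "head and neck",
    2: "face",
    3: "thorax",
    4: "abdomen and pelvic cavity",
    5: "limbs and pelvis",
    6: "external and others",
}

MECHANISM_NAMES = {
    1: "stab",
    2: "violence",
    3: "blunt",
    4: "fall",
    5: "motor_vehicle",
    6: "firearm",
}


class CohortValidationError(ValueError):
    """Raised when registry rows violate the data-model invariants.

    Carries the collected per-row messages in :attr:`errors`.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class NontraumaticMechanismError(ValueError):
    """Raised when an E-code falls outside the six traumatic mechanism
    families (e.g. drowning, poisoning, burns, overexertion)."""


class VitalCodingConfigError(ValueError):
    """Raised for overlapping or non-monotone vital-sign coding intervals."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InjuryRecord:
    """One coded injury: a six-digit AIS 2005 predot code plus severity digit."""

    patient_id: str
    predot: str
    severity: int

    def __post_init__(self) -> None:
        if not (isinstance(self.predot, str) and len(self.predot) == 6
                and self.predot.isdigit() and self.predot[0] != "0"):
            raise ValueError(
                f"predot must be 6 digits with leading digit 1-9, got {self.predot!r}")
        if self.severity not in VALID_SEVERITIES:
            raise ValueError(
                f"severity must be in {sorted(VALID_SEVERITIES)}, got {self.severity!r}")


@dataclass
class PatientRecord:
    """One trauma admission with physiology, mechanism, outcome and injuries."""

    patient_id: str
    age: int
    gender: str  # "male" | "female"
    gcs: int
    sbp: float
    pulse: float
    rr: float
    icu_days: float
    vent_days: float
    los_days: float
    outcome: str  # "died" | "survived"
    hospital_id: str
    injuries: list[InjuryRecord] = field(default_factory=list)
    ecode: str | None = None
    mechanism: int | None = None
    dx_codes: list[str] | None = None
    cci: int | None = None
    transfer_flag: bool = False
    dead_on_arrival_flag: bool = False
    ed_only_flag: bool = False

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when the record is valid)."""
        problems = []
        if self.outcome not in ("died", "survived"):
            problems.append(f"outcome must be died/survived, got {self.outcome!r}")
        if self.gender not in ("male", "female"):
            problems.append(f"gender must be male/female, got {self.gender!r}")
        if self.ecode is None and self.mechanism is None:
            problems.append("one of ecode/mechanism is required")
        if self.mechanism is not None and self.mechanism not in MECHANISM_NAMES:
            problems.append(f"mechanism must be 1-6, got {self.mechanism!r}")
        if self.dx_codes is None and self.cci is None:
            problems.append("one of dx_codes/cci is required")
        if not self.injuries:
            problems.append("injuries must be nonempty")
        if not 3 <= self.gcs <= 15:
            problems.append(f"gcs must be 3-15, got {self.gcs!r}")
        for name in ("sbp", "pulse", "rr", "icu_days", "vent_days", "los_days"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v < 0:
                problems.append(f"{name} must be nonnegative, got {v!r}")
        return problems

    @property
    def died(self) -> bool:
        return self.outcome == "died"

    def resolved_mechanism(self) -> int:
        """Mechanism family 1-6, mapped from the E-code when not given directly."""
        if self.mechanism is not None:
            return self.mechanism
        return map_mechanism(self.ecode)

    def resolved_cci(self) -> int:
        """Charlson index, computed from dx_codes when not precomputed."""
        if self.cci is not None:
            return self.cci
        return charlson_index(self.dx_codes or [])


@dataclass
class ExclusionLedger:
    """Ordered per-rule exclusion counts with a conservation identity."""

    steps: list[tuple[str, int]]
    n_input: int
    n_output: int

    def __post_init__(self) -> None:
        total = sum(n for _, n in self.steps)
        if self.n_input != self.n_output + total:
            raise ValueError(
                f"ledger identity violated: {self.n_input} != {self.n_output} + {total}")

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_output": self.n_output,
             "steps": [{"rule": r, "n_excluded": n} for r, n in self.steps]},
            indent=2)


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint derivation / fitting / validation patient-id sets."""

    derivation: frozenset[str]
    fitting: frozenset[str]
    validation: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        parts = (self.derivation, self.fitting, self.validation)
        total = sum(len(p) for p in parts)
        union = self.derivation | self.fitting | self.validation
        if total != len(union):
            raise ValueError("split partitions overlap")

    def subset(self, cohort: Sequence[PatientRecord], which: str) -> list[PatientRecord]:
        ids = getattr(self, which)
        return [p for p in cohort if p.patient_id in ids]


# ---------------------------------------------------------------------------
# Packaged lookup tables
# ---------------------------------------------------------------------------


def _load_data(name: str) -> dict:
    with resources.files("trimp.data").joinpath(name).open("r") as fh:
        return json.load(fh)


_ECODE_TABLE = _load_data("ecode_mechanism.json")
_CHARLSON_TABLE = _load_data("charlson_deyo.json")
_VITAL_DEFAULTS = _load_data("vital_coding.json")


# ---------------------------------------------------------------------------
# Mechanism coding
# ---------------------------------------------------------------------------


def _parse_ecode(ecode: str) -> float:
    """Normalize an ICD-9-CM E-code to its numeric part (E955.2 -> 955.2).

    Accepts 'E955.2', '955.2', and the dotless registry form 'E9552'.
    """
    if not isinstance(ecode, str):
        raise ValueError(f"E-code must be a string, got {type(ecode).__name__}")
    s = ecode.strip().upper().lstrip("E")
    if "." in s:
        whole, _, frac = s.partition(".")
        frac = frac[:1]
    elif len(s) == 4:
        whole, frac = s[:3], s[3]
    else:
        whole, frac = s, ""
    if not (whole.isdigit() and len(whole) == 3 and (frac == "" or frac.isdigit())):
        raise ValueError(f"syntactically invalid E-code: {ecode!r}")
    return int(whole) + (int(frac) / 10 if frac else 0.0)


def map_mechanism(ecode: str) -> int:
    """Map an ICD-9-CM E-code to the mechanism family 1-6.

    1 stab, 2 violence (struck by/against), 3 blunt, 4 fall,
    5 motor vehicle crash, 6 firearm. E-codes outside the six families
    (drowning, poisoning, burns, suffocation, overexertion, ...) raise
    :class:`NontraumaticMechanismError`, which the exclusion cascade consumes.
    """
    value = _parse_ecode(ecode)
    for fam, spec in _ECODE_TABLE["families"].items():
        for lo, hi in spec["ranges"]:
            if lo <= value <= hi:
                return int(fam)
    raise NontraumaticMechanismError(
        f"E-code {ecode!r} is outside the six traumatic mechanism families")


def mechanism_or_none(ecode: str) -> int | None:
    """As :func:`map_mechanism` but returning None for excluded mechanisms."""
    try:
        return map_mechanism(ecode)
    except NontraumaticMechanismError:
        return None


# ---------------------------------------------------------------------------
# AIS chapter -> ISS body region
# ---------------------------------------------------------------------------

# AIS 2005 chapters (leading predot digit): 1 head, 2 face, 3 neck, 4 thorax,
# 5 abdomen, 6 spine, 7 upper extremity, 8 lower extremity/pelvis, 9 external.
_CHAPTER_REGION = {
    "1": REGION_HEAD_NECK,
    "2": REGION_FACE,
    "3": REGION_HEAD_NECK,
    "4": REGION_THORAX,
    "5": REGION_ABDOMEN,
    "7": REGION_LIMBS,
    "8": REGION_LIMBS,
    "9": REGION_EXTERNAL,
}

# Spine codes (chapter 6) carry the vertebral level in the fourth predot
# digit: 2 cervical, 4 thoracic, 6 lumbar (e.g. 640462 is thoracic cord).
_SPINE_LEVEL_REGION = {"2": REGION_HEAD_NECK, "4": REGION_THORAX, "6": REGION_ABDOMEN}


def ais_to_iss_region(predot: str) -> int:
    """ISS body region (1-6) for an AIS 2005 predot code.

    1 head/neck, 2 face, 3 thorax, 4 abdomen and pelvic contents,
    5 limbs and bony pelvis, 6 external/other. Spine injuries are assigned
    by vertebral level; an unrecognized level digit defaults to head/neck
    (cervical), the most common spine presentation.
    """
    if not (isinstance(predot, str) and len(predot) == 6 and predot.isdigit()):
        raise ValueError(f"invalid predot code {predot!r}")
    chapter = predot[0]
    if chapter == "6":
        return _SPINE_LEVEL_REGION.get(predot[3], REGION_HEAD_NECK)
    try:
        return _CHAPTER_REGION[chapter]
    except KeyError:
        raise ValueError(f"unmappable AIS chapter digit {chapter!r} in {predot!r}") from None


# ---------------------------------------------------------------------------
# Charlson comorbidity index (Deyo ICD-9 mapping)
# ---------------------------------------------------------------------------


def _normalize_dx(code: str) -> str:
    return code.strip().upper().replace(".", "")


def charlson_index(dx_codes: Iterable[str]) -> int:
    """Charlson Comorbidity Index from ICD-9-CM diagnosis codes.

    Uses the packaged Deyo prefix mapping; each condition counts once
    regardless of how many codes match it, the standard severity hierarchies
    apply (e.g. metastatic disease supersedes other malignancy), and
    unrecognized codes contribute zero.
    """
    codes = [_normalize_dx(c) for c in dx_codes if c and c.strip()]
    present: set[str] = set()
    for cond, spec in _CHARLSON_TABLE["conditions"].items():
        prefixes = tuple(spec["prefixes"])
        if any(code.startswith(prefixes) for code in codes):
            present.add(cond)
    for severe, mild in _CHARLSON_TABLE["hierarchies"]:
        if severe in present:
            present.discard(mild)
    return sum(_CHARLSON_TABLE["conditions"][c]["weight"] for c in present)


# ---------------------------------------------------------------------------
# Vital-sign ordinal coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VitalCodingConfig:
    """Interval tables mapping SBP/pulse/RR measurements to ordinal codes.

    Each table is a sequence of ``(lo, hi, code)`` with ``hi=None`` meaning
    unbounded; a measurement gets the code of the first interval whose upper
    bound it does not exceed. Code 0 marks the physiologically normal band and
    codes must rise monotonically away from it (a "valley" shape), so that
    larger codes always mean worse derangement.
    """

    sbp: tuple[tuple[float, float | None, int], ...]
    pulse: tuple[tuple[float, float | None, int], ...]
    rr: tuple[tuple[float, float | None, int], ...]

    def __post_init__(self) -> None:
        for name in ("sbp", "pulse", "rr"):
            _validate_interval_table(name, getattr(self, name))

    @classmethod
    def default(cls) -> "VitalCodingConfig":
        return cls(
            sbp=tuple(tuple(row) for row in _VITAL_DEFAULTS["sbp"]),
            pulse=tuple(tuple(row) for row in _VITAL_DEFAULTS["pulse"]),
            rr=tuple(tuple(row) for row in _VITAL_DEFAULTS["rr"]),
        )


def _validate_interval_table(name, table) -> None:
    if not table:
        raise VitalCodingConfigError(f"{name}: empty interval table")
    prev_hi = -math.inf
    for lo, hi, code in table:
        if hi is not None and lo > hi:
            raise VitalCodingConfigError(f"{name}: interval ({lo}, {hi}) is inverted")
        if lo <= prev_hi:
            raise VitalCodingConfigError(f"{name}: overlapping intervals at lo={lo}")
        prev_hi = math.inf if hi is None else hi
        if code < 0:
            raise VitalCodingConfigError(f"{name}: negative code {code}")
    if table[-1][1] is not None:
        raise VitalCodingConfigError(f"{name}: last interval must be unbounded")
    codes = [code for _, _, code in table]
    if 0 not in codes:
        raise VitalCodingConfigError(f"{name}: no interval coded 0 (normal)")
    first0, last0 = codes.index(0), len(codes) - 1 - codes[::-1].index(0)
    left, right = codes[: first0 + 1], codes[last0:]
    if any(a < b for a, b in zip(left, left[1:])) or any(
            a > b for a, b in zip(right, right[1:])):
        raise VitalCodingConfigError(
            f"{name}: codes must decrease monotonically to the normal band "
            f"and increase after it, got {codes}")


def _code_one(value: float, table) -> int:
    if value < 0 or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"measurement must be nonnegative, got {value!r}")
    for _, hi, code in table:
        if hi is None or value <= hi:
            return code
    raise AssertionError("unreachable: last interval is unbounded")


def code_vitals(sbp: float, pulse: float, rr: float,
                config: VitalCodingConfig | None = None) -> tuple[int, int, int]:
    """Ordinal derangement codes ``(sbp_code, pulse_code, rr_code)``.

    0 = normal, larger = worse, per the configured interval tables.
    """
    cfg = config or VitalCodingConfig.default()
    return (_code_one(sbp, cfg.sbp), _code_one(pulse, cfg.pulse), _code_one(rr, cfg.rr))


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = [
    "patient_id", "age", "gender", "ecode", "mechanism", "gcs", "sbp", "pulse",
    "rr", "icu_days", "vent_days", "los_days", "cci", "dx_codes", "outcome",
    "hospital_id", "transfer_flag", "dead_on_arrival_flag", "ed_only_flag",
]
INJURY_COLUMNS = ["patient_id", "predot", "severity"]

_BOOL_TRUE = {"1", "true", "yes", "y"}


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in _BOOL_TRUE


def read_cohort(patients_path, injuries_path, dialect: str = ",") -> list[PatientRecord]:
    """Read a cohort from the two-file registry dialect.

    ``dialect`` is the field delimiter (comma default, tab accepted). All
    malformed rows are collected and reported together, with line numbers, in
    a single :class:`CohortValidationError`; injuries referencing unknown
    patients are orphan errors.
    """
    errors: list[str] = []
    patients: dict[str, PatientRecord] = {}

    with open(patients_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect)
        missing = set(PATIENT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CohortValidationError(
                [f"{patients_path}: missing columns {sorted(missing)}"])
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = row["patient_id"].strip()
                if not pid:
                    raise ValueError("empty patient_id")
                if pid in patients:
                    raise ValueError(f"duplicate patient_id {pid!r}")
                dx_raw = row["dx_codes"].strip()
                rec = PatientRecord(
                    patient_id=pid,
                    age=int(row["age"]),
                    gender=row["gender"].strip().lower(),
                    ecode=row["ecode"].strip() or None,
                    mechanism=int(row["mechanism"]) if row["mechanism"].strip() else None,
                    gcs=int(row["gcs"]),
                    sbp=float(row["sbp"]),
                    pulse=float(row["pulse"]),
                    rr=float(row["rr"]),
                    icu_days=float(row["icu_days"]),
                    vent_days=float(row["vent_days"]),
                    los_days=float(row["los_days"]),
                    cci=int(row["cci"]) if row["cci"].strip() else None,
                    dx_codes=dx_raw.split(";") if dx_raw else None,
                    outcome=row["outcome"].strip().lower(),
                    hospital_id=row["hospital_id"].strip(),
                    transfer_flag=_parse_bool(row["transfer_flag"]),
                    dead_on_arrival_flag=_parse_bool(row["dead_on_arrival_flag"]),
                    ed_only_flag=_parse_bool(row["ed_only_flag"]),
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"{patients_path}:{lineno}: {exc}")
                continue
            patients[pid] = rec

    with open(injuries_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect)
        missing = set(INJURY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CohortValidationError(
                [f"{injuries_path}: missing columns {sorted(missing)}"])
        for lineno, row in enumerate(reader, start=2):
            pid = row["patient_id"].strip()
            if pid not in patients:
                errors.append(f"{injuries_path}:{lineno}: orphan injury for "
                              f"unknown patient {pid!r}")
                continue
            try:
                inj = InjuryRecord(patient_id=pid, predot=row["predot"].strip(),
                                   severity=int(row["severity"]))
            except ValueError as exc:
                errors.append(f"{injuries_path}:{lineno}: {exc}")
                continue
            patients[pid].injuries.append(inj)

    records = list(patients.values())
    for rec in records:
        for problem in rec.validate():
            # nonempty-injuries / coding invariants surface here
            errors.append(f"patient {rec.patient_id}: {problem}")
    if errors:
        raise CohortValidationError(errors)
    return records


def write_cohort(cohort: Sequence[PatientRecord], patients_path, injuries_path,
                 dialect: str = ",") -> None:
    """Write a cohort in the two-file registry dialect (round-trips with
    :func:`read_cohort`)."""
    with open(patients_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect)
        writer.writerow(PATIENT_COLUMNS)
        for p in cohort:
            writer.writerow([
                p.patient_id, p.age, p.gender, p.ecode or "",
                p.mechanism if p.mechanism is not None else "",
                p.gcs, p.sbp, p.pulse, p.rr, p.icu_days, p.vent_days, p.los_days,
                p.cci if p.cci is not None else "",
                ";".join(p.dx_codes) if p.dx_codes is not None else "",
                p.outcome, p.hospital_id,
                int(p.transfer_flag), int(p.dead_on_arrival_flag), int(p.ed_only_flag),
            ])
    with open(injuries_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect)
        writer.writerow(INJURY_COLUMNS)
        for p in cohort:
            for inj in p.injuries:
                writer.writerow([p.patient_id, inj.predot, inj.severity])


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionConfig:
    """Knobs of the exclusion cascade."""

    max_age: int = 89
    min_age: int = 1
    min_hospital_volume: int = 500  # trauma patients per calendar year
    n_years: int = 1


def _rule_mechanism(p: PatientRecord, cfg) -> bool:
    if p.mechanism is not None:
        return False
    if p.ecode is None:
        return False  # handled by the missing-cause rule
    try:
        return mechanism_or_none(p.ecode) is None
    except ValueError:
        return False  # syntactically bad codes count as missing cause


def _rule_missing_cause(p: PatientRecord, cfg) -> bool:
    if p.mechanism is not None:
        return False
    if p.ecode is None:
        return True
    try:
        _parse_ecode(p.ecode)
        return False
    except ValueError:
        return True


def _rule_missing_invalid(p: PatientRecord, cfg) -> bool:
    if p.gender not in ("male", "female"):
        return True
    if p.outcome not in ("died", "survived"):
        return True
    if p.age is None or p.age < 0:
        return True
    if p.los_days is None or (isinstance(p.los_days, float)
                              and math.isnan(p.los_days)) or p.los_days < 0:
        return True
    return False


# (rule_name, predicate) in the order the cascade applies them; counts are
# order-dependent because each patient is excluded by the first matching rule.
_EXCLUSION_RULES = [
    ("nontraumatic_mechanism", _rule_mechanism),
    ("missing_cause_of_injury", _rule_missing_cause),
    ("missing_or_invalid_data", _rule_missing_invalid),
    ("age_over_max", lambda p, cfg: p.age > cfg.max_age),
    ("age_under_min", lambda p, cfg: p.age < cfg.min_age),
    ("ed_only", lambda p, cfg: p.ed_only_flag),
    ("dead_on_arrival", lambda p, cfg: p.dead_on_arrival_flag),
    ("transferred", lambda p, cfg: p.transfer_flag),
    ("severity_9_only", lambda p, cfg: bool(p.injuries)
        and all(i.severity == 9 for i in p.injuries)),
]


def apply_exclusions(cohort: Sequence[PatientRecord],
                     config: ExclusionConfig | None = None,
                     ) -> tuple[list[PatientRecord], ExclusionLedger]:
    """Apply the sequential exclusion cascade and account for every patient.

    Rules, in order: nontraumatic/overexertion/burn mechanism; missing cause
    of injury; missing/invalid age, gender, length of stay or outcome; age
    above/below bounds; emergency-department-only; dead on arrival;
    transferred; all injuries severity 9; low-volume hospital. Each patient is
    charged to the first rule it trips, so per-rule counts are order-dependent
    and ``n_input = n_output + sum(excluded)`` always holds.
    """
    cfg = config or ExclusionConfig()
    remaining = list(cohort)
    steps: list[tuple[str, int]] = []
    for name, rule in _EXCLUSION_RULES:
        kept, dropped = [], 0
        for p in remaining:
            if rule(p, cfg):
                dropped += 1
            else:
                kept.append(p)
        steps.append((name, dropped))
        remaining = kept

    # hospital-volume rule: counted on what survived the patient-level rules
    threshold = cfg.min_hospital_volume * cfg.n_years
    volume: dict[str, int] = {}
    for p in remaining:
        volume[p.hospital_id] = volume.get(p.hospital_id, 0) + 1
    kept = [p for p in remaining if volume[p.hospital_id] >= threshold]
    steps.append(("low_volume_hospital", len(remaining) - len(kept)))

    ledger = ExclusionLedger(steps=steps, n_input=len(cohort), n_output=len(kept))
    return kept, ledger


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_cohort(cohort: Sequence[PatientRecord],
                 fractions: Sequence[float] = (0.666, 0.167, 0.167),
                 seed: int = 0) -> CohortSplit:
    """Random derivation/fitting/validation partition by patient.

    Reproducible under ``seed``; partition sizes are the largest-remainder
    apportionment of ``n * fraction`` so each is within one patient of ideal.
    """
    if not cohort:
        raise ValueError("cannot split an empty cohort")
    if len(fractions) != 3:
        raise ValueError("exactly three fractions required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(cohort)
    ideal = [n * f for f in fractions]
    sizes = [int(x) for x in ideal]
    remainders = sorted(range(3), key=lambda i: ideal[i] - sizes[i], reverse=True)
    for i in range(n - sum(sizes)):
        sizes[remainders[i % 3]] += 1

    ids = sorted(p.patient_id for p in cohort)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return CohortSplit(
        derivation=frozenset(shuffled[:a]),
        fitting=frozenset(shuffled[a:b]),
        validation=frozenset(shuffled[b:]),
        seed=seed,
    )
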