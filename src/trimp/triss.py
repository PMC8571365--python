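"""TRISS comparator: ISS, Revised Trauma Score, and survival probability.

ISS is the sum of squares of the three highest AIS severities taken over the
six body regions (75 whenever any injury is severity 6). The Revised Trauma
Score is the weighted sum of 0-4 coded GCS, systolic blood pressure and
respiratory rate. TRISS combines RTS, ISS and an age index in a logistic
survival model with separate blunt and penetrating coefficient sets; the
packaged set is the classic Major Trauma Outcome Study calibration, and any
same-shaped JSON (including age-band codings) may be substituted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .cohort import InjuryRecord, PatientRecord, ais_to_iss_region

PENETRATING_MECHANISMS = frozenset({1, 6})  # stab, firearm


class ISSError(ValueError):
    """ISS could not be computed (all severities unknown)."""


@dataclass(frozen=True)
class ISSValue:
    iss: int
    top_regions: tuple[tuple[int, int], ...]  # (region, max severity) pairs used


@dataclass(frozen=True)
class TRISSCoefficients:
    """Blunt/penetrating logistic constants plus RTS weights and age coding."""

    rts_weights: dict
    blunt: dict
    penetrating: dict
    age_threshold: int | None = None
    age_bands: tuple[tuple[float, float, int], ...] | None = None
    vintage: str = "custom"

    def age_index(self, age: float) -> int:
        if self.age_bands is not None:
            for lo, hi, idx in self.age_bands:
                if lo <= age <= hi:
                    return idx
            raise ValueError(f"age {age} outside the configured bands")
        return int(age > self.age_threshold)

    @classmethod
    def from_json(cls, path) -> "TRISSCoefficients":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "TRISSCoefficients":
        bands = payload.get("age_bands")
        return cls(
            rts_weights=payload["rts_weights"],
            blunt=payload["blunt"],
            penetrating=payload["penetrating"],
            age_threshold=payload.get("age_threshold"),
            age_bands=tuple(tuple(b) for b in bands) if bands else None,
            vintage=payload.get("vintage", "custom"),
        )

    @classmethod
    def default(cls) -> "TRISSCoefficients":
        with resources.files("trimp.data").joinpath(
                "triss_coefficients.json").open("r") as fh:
            return cls._from_payload(json.load(fh))


# ---------------------------------------------------------------------------
# ISS
# ---------------------------------------------------------------------------


def iss(injuries: Sequence[InjuryRecord]) -> ISSValue:
    """Injury Severity Score from a patient's AIS-coded injuries.

    Severity-9 (unknown) injuries are ignored; if nothing else remains the
    ISS value cannot be calculated and :class:`ISSError` is raised. Any
    severity-6 injury forces the maximal score 75. Order-invariant.
    """
    usable = [i for i in injuries if i.severity != 9]
    if not usable:
        raise ISSError("ISS value could not be calculated: "
                       "all injuries have unknown severity (9)")
    if any(i.severity == 6 for i in usable):
        worst = max(usable, key=lambda i: i.severity)
        return ISSValue(iss=75, top_regions=(
            (ais_to_iss_region(worst.predot), 6),))

    region_max: dict[int, int] = {}
    for inj in usable:
        region = ais_to_iss_region(inj.predot)
        region_max[region] = max(region_max.get(region, 0), inj.severity)
    top = sorted(region_max.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
    return ISSValue(iss=sum(sev * sev for _, sev in top),
                    top_regions=tuple(top))


# ---------------------------------------------------------------------------
# Revised Trauma Score
# ---------------------------------------------------------------------------

# standard 0-4 coded intervals: (upper bound inclusive, code), ascending
_GCS_CODES = ((3, 0), (5, 1), (8, 2), (12, 3), (15, 4))
_SBP_CODES = ((0, 0), (49, 1), (75, 2), (89, 3), (math.inf, 4))
_RR_CODES = ((0, 0), (5, 1), (9, 2), (29, 4), (math.inf, 3))  # >29 codes 3


def _rts_code(value: float, table) -> int:
    for hi, code in table:
        if value <= hi:
            return code
    raise AssertionError("unreachable")


def rts(gcs: int, sbp: float, rr: float,
        coefficients: TRISSCoefficients | None = None) -> float:
    """Revised Trauma Score: weighted sum of coded GCS, SBP and RR."""
    if not 3 <= gcs <= 15:
        raise ValueError(f"gcs must be 3-15, got {gcs}")
    if sbp < 0 or rr < 0:
        raise ValueError("sbp and rr must be nonnegative")
    coefs = coefficients or TRISSCoefficients.default()
    w = coefs.rts_weights
    return (w["gcs"] * _rts_code(gcs, _GCS_CODES)
            + w["sbp"] * _rts_code(sbp, _SBP_CODES)
            + w["rr"] * _rts_code(rr, _RR_CODES))


def rts_codes(gcs: int, sbp: float, rr: float) -> tuple[int, int, int]:
    """The raw 0-4 codes behind :func:`rts` (useful for table oracles)."""
    return (_rts_code(gcs, _GCS_CODES), _rts_code(sbp, _SBP_CODES),
            _rts_code(rr, _RR_CODES))


# ---------------------------------------------------------------------------
# TRISS survival probability
# ---------------------------------------------------------------------------


def is_penetrating(mechanism: int) -> bool:
    """Mechanism dichotomization: stab and firearm are penetrating; violence,
    blunt, fall and motor vehicle crash are blunt."""
    if mechanism not in range(1, 7):
        raise ValueError(f"mechanism must be 1-6, got {mechanism}")
    return mechanism in PENETRATING_MECHANISMS


def triss_survival(patient: PatientRecord,
                   coefficients: TRISSCoefficients | None = None) -> float:
    """TRISS survival probability for one patient.

    ``b = b0 + b_rts*RTS + b_iss*ISS + b_age*AgeIndex`` with the
    mechanism-specific coefficient set; survival probability is the logistic
    transform of ``b``.
    """
    coefs = coefficients or TRISSCoefficients.default()
    mech = patient.resolved_mechanism()
    cset = coefs.penetrating if is_penetrating(mech) else coefs.blunt
    score = iss(patient.injuries).iss
    r = rts(patient.gcs, patient.sbp, patient.rr, coefs)
    b = (cset["b0"] + cset["b_rts"] * r + cset["b_iss"] * score
         + cset["b_age"] * coefs.age_index(patient.age))
    return 1.0 / (1.0 + math.exp(-b))
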