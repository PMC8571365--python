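"""The 19-predictor TRIMP probit mortality model.

The feature vector combines anatomy (the five worst WMDP values, their
interaction, a same-region flag, and the number of injured body regions with
its fractional-polynomial companion NBR^0.382), physiological reserve (age,
gender, Charlson index, injury mechanism) and physiological response (GCS,
ICU admission, mechanical ventilation, coded vital signs). The death
probability is the standard normal CDF of the linear predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import PatientRecord, VitalCodingConfig, ais_to_iss_region, code_vitals
from .wmdp import WMDPEntry, pmr, wmdp_lookup

NBR_EXPONENT = 0.382  # fixed fractional-polynomial power for the NBR term

FEATURE_NAMES = (
    "wmdp1", "wmdp2", "wmdp3", "wmdp4", "wmdp5", "interaction", "same_region",
    "nbr", "nbr_fp", "age", "male", "cci", "mechanism", "gcs", "icu", "vent",
    "sbp_code", "pulse_code", "rr_code",
)
COEFFICIENT_NAMES = ("constant",) + FEATURE_NAMES


class MissingCodeError(KeyError):
    """A patient's predot code is absent from the WMDP table."""


class ModelFitError(ValueError):
    """Probit fitting failed (separation or rank deficiency)."""


@dataclass(frozen=True)
class TRIMPFeatures:
    """The 19-element predictor vector for one patient."""

    patient_id: str
    wmdp1: float
    wmdp2: float
    wmdp3: float
    wmdp4: float
    wmdp5: float
    interaction: float
    same_region: int
    nbr: int
    nbr_fp: float
    age: float
    male: int
    cci: int
    mechanism: int
    gcs: int
    icu: int
    vent: int
    sbp_code: int
    pulse_code: int
    rr_code: int

    def __post_init__(self) -> None:
        w = (self.wmdp1, self.wmdp2, self.wmdp3, self.wmdp4, self.wmdp5)
        if any(a < b for a, b in zip(w, w[1:])) or w[4] < 0:
            raise ValueError(f"wmdp values must be descending and nonnegative: {w}")
        if abs(self.interaction - self.wmdp1 * self.wmdp2) > 1e-12:
            raise ValueError("interaction must equal wmdp1 * wmdp2")
        if abs(self.nbr_fp - self.nbr ** NBR_EXPONENT) > 1e-12:
            raise ValueError(f"nbr_fp must equal nbr**{NBR_EXPONENT}")
        if self.same_region not in (0, 1):
            raise ValueError("same_region must be 0 or 1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


@dataclass(frozen=True)
class CoefficientTable:
    """Probit coefficients c0..c19 with robust standard errors."""

    estimates: tuple[float, ...]  # ordered per COEFFICIENT_NAMES
    robust_se: tuple[float, ...]
    n_fit: int
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        if len(self.estimates) != 20 or len(self.robust_se) != 20:
            raise ValueError("exactly 20 coefficients and standard errors required")

    def __getitem__(self, name: str) -> float:
        return self.estimates[COEFFICIENT_NAMES.index(name)]

    def se(self, name: str) -> float:
        return self.robust_se[COEFFICIENT_NAMES.index(name)]

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {n: {"estimate": e, "robust_se": s}
                for n, e, s in zip(COEFFICIENT_NAMES, self.estimates, self.robust_se)}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"n_fit": self.n_fit, "coefficients": self.as_dict()}, fh,
                      indent=2)

    @classmethod
    def from_mapping(cls, coefficients: Mapping[str, Mapping[str, float]],
                     n_fit: int, log_likelihood: float | None = None,
                     ) -> "CoefficientTable":
        missing = set(COEFFICIENT_NAMES) - set(coefficients)
        if missing:
            raise ValueError(f"missing coefficients: {sorted(missing)}")
        return cls(
            estimates=tuple(float(coefficients[n]["estimate"]) for n in COEFFICIENT_NAMES),
            robust_se=tuple(float(coefficients[n]["robust_se"]) for n in COEFFICIENT_NAMES),
            n_fit=n_fit, log_likelihood=log_likelihood)

    @classmethod
    def from_json(cls, path) -> "CoefficientTable":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls.from_mapping(payload["coefficients"], int(payload.get("n_fit", 0)))


@dataclass(frozen=True)
class RiskPrediction:
    patient_id: str
    eta: float
    p_death: float

    @property
    def p_survival(self) -> float:
        return 1.0 - self.p_death


def published_coefficients() -> CoefficientTable:
    """The packaged published coefficient table (refit on 199,840 patients)."""
    with resources.files("trimp.data").joinpath(
            "trimp_published_coefficients.json").open("r") as fh:
        payload = json.load(fh)
    return CoefficientTable.from_mapping(payload["coefficients"], payload["n_fit"])


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------


def _injury_rank_key(injury, score: float):
    # descending score, then higher severity digit, then predot lexicographic
    return (-score, -injury.severity, injury.predot)


def build_features(patient: PatientRecord,
                   wmdp_table: Sequence[WMDPEntry] | Mapping[str, float],
                   vital_config: VitalCodingConfig | None = None,
                   on_missing: str = "error") -> TRIMPFeatures:
    """Assemble the predictor vector for one patient.

    Injuries are ranked by WMDP descending (ties broken by higher severity
    digit, then predot); the top five scores are kept, zero-padded when the
    patient has fewer. ``on_missing`` controls codes absent from the table:
    ``"error"`` (default) raises :class:`MissingCodeError`, ``"pmr"`` falls
    back to the patient's age-based possible mortality rate.
    """
    table = wmdp_table if isinstance(wmdp_table, Mapping) else wmdp_lookup(wmdp_table)
    if on_missing not in ("error", "pmr"):
        raise ValueError(f"on_missing must be 'error' or 'pmr', got {on_missing!r}")

    scored = []
    for inj in patient.injuries:
        if inj.predot in table:
            score = table[inj.predot]
        elif on_missing == "pmr":
            score = pmr(patient.age)
        else:
            raise MissingCodeError(
                f"predot {inj.predot!r} of patient {patient.patient_id} "
                f"is absent from the WMDP table")
        scored.append((inj, float(score)))
    scored.sort(key=lambda pair: _injury_rank_key(*pair))

    top = [s for _, s in scored[:5]]
    w = top + [0.0] * (5 - len(top))
    same_region = 0
    if len(scored) >= 2:
        r1 = ais_to_iss_region(scored[0][0].predot)
        r2 = ais_to_iss_region(scored[1][0].predot)
        same_region = int(r1 == r2)
    regions = {ais_to_iss_region(inj.predot) for inj, _ in scored}
    nbr = len(regions)

    sbp_code, pulse_code, rr_code = code_vitals(
        patient.sbp, patient.pulse, patient.rr, vital_config)
    return TRIMPFeatures(
        patient_id=patient.patient_id,
        wmdp1=w[0], wmdp2=w[1], wmdp3=w[2], wmdp4=w[3], wmdp5=w[4],
        interaction=w[0] * w[1],
        same_region=same_region,
        nbr=nbr, nbr_fp=nbr ** NBR_EXPONENT,
        age=float(patient.age),
        male=int(patient.gender == "male"),
        cci=patient.resolved_cci(),
        mechanism=patient.resolved_mechanism(),
        gcs=patient.gcs,
        icu=int(patient.icu_days > 0),
        vent=int(patient.vent_days > 0),
        sbp_code=sbp_code, pulse_code=pulse_code, rr_code=rr_code,
    )


def features_frame(features: Sequence[TRIMPFeatures]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame (columns per FEATURE_NAMES)."""
    data = np.array([f.as_array() for f in features])
    frame = pd.DataFrame(data, columns=list(FEATURE_NAMES))
    frame.insert(0, "patient_id", [f.patient_id for f in features])
    return frame


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def linear_predictor(features: TRIMPFeatures,
                     coefficients: CoefficientTable) -> float:
    """Probit index: intercept plus the coefficient-weighted feature sum."""
    return float(coefficients.estimates[0]
                 + np.dot(coefficients.estimates[1:], features.as_array()))


def predict(patients: Sequence[PatientRecord],
            wmdp_table: Sequence[WMDPEntry] | Mapping[str, float],
            coefficients: CoefficientTable | None = None,
            vital_config: VitalCodingConfig | None = None,
            on_missing: str = "error") -> list[RiskPrediction]:
    """Death-risk predictions, one per patient, order preserved.

    ``p_death`` is the standard normal CDF of the probit index; the packaged
    published coefficients are the default.
    """
    coefs = coefficients or published_coefficients()
    table = wmdp_table if isinstance(wmdp_table, Mapping) else wmdp_lookup(wmdp_table)
    out = []
    for p in patients:
        f = build_features(p, table, vital_config, on_missing)
        eta = linear_predictor(f, coefs)
        out.append(RiskPrediction(patient_id=p.patient_id, eta=eta,
                                  p_death=float(norm.cdf(eta))))
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_trimp(features: Sequence[TRIMPFeatures],
              outcomes: Sequence[int | bool],
              min_events: int = 50) -> CoefficientTable:
    """Maximum-likelihood probit fit with robust (HC1 sandwich) standard errors.

    Requires at least ``min_events`` deaths and survivals and a full-rank
    design; separation and rank deficiency raise :class:`ModelFitError`
    naming the offending columns.
    """
    import statsmodels.api as sm

    y = np.asarray(outcomes, dtype=float)
    if len(y) != len(features):
        raise ValueError("features and outcomes must align")
    n_events = int(y.sum())
    if n_events < min_events or len(y) - n_events < min_events:
        raise ModelFitError(
            f"need at least {min_events} events and non-events, got "
            f"{n_events} deaths / {len(y) - n_events} survivals (separation risk)")

    X = np.column_stack([np.ones(len(y))] +
                        [np.array([getattr(f, n) for f in features], dtype=float)
                         for n in FEATURE_NAMES])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that add no rank when appended incrementally
        offending = []
        kept = X[:, :1]
        for j, name in enumerate(COEFFICIENT_NAMES[1:], start=1):
            trial = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                offending.append(name)
            else:
                kept = trial
        raise ModelFitError(f"rank-deficient design; dependent columns: {offending}")

    try:
        result = sm.Probit(y, X).fit(disp=False, maxiter=200, cov_type="HC1")
    except Exception as exc:  # statsmodels PerfectSeparation and friends
        raise ModelFitError(f"probit fit failed: {exc}") from exc
    if not result.mle_retvals.get("converged", True):
        raise ModelFitError("probit fit did not converge")

    return CoefficientTable(
        estimates=tuple(float(b) for b in result.params),
        robust_se=tuple(float(s) for s in result.bse),
        n_fit=len(y),
        log_likelihood=float(result.llf),
    )
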