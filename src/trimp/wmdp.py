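"""Per-AIS-predot-code weighted median death probability (WMDP) derivation.

Each six-digit predot code receives an empirical death-propensity score built
from the derivation partition of the registry:

* **SMR** — the code's mortality among patients whose *only* injury carries
  it (deaths D1 over bearers T1): the cleanest signal of the code's own
  lethality.
* **TDP** — among multiple-injury bearers, each patient contributes a
  per-injury death probability equal to the death indicator divided by an
  attribution constant (the mean number of injuries per patient scaled by
  0.618, default 4.404 x 0.618 = 2.721672), spreading a multi-trauma death
  across its injuries. The up-to-three largest TDP values per code are kept
  (their count is ``n_u``).
* **WMDP** — the weighted median of the candidate set {SMR} U {top TDPs},
  with weight ``smr_weight`` (default 0.618) on SMR and the remainder split
  evenly over the TDP candidates. Codes never seen as an isolated injury use
  the TDP candidates alone, with weights renormalized.
* **PMR fallback** — a code with no observed deaths anywhere falls back to
  the median possible mortality rate of its bearers, where
  ``PMR(age) = 0.01202 * exp(0.0719 * age)`` is an age-trend substitute for
  the unobserved crude death rate.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord

PMR_BASE = 0.01202
PMR_SLOPE = 0.0719  # per year of age
MEAN_INJURIES_PER_PATIENT = 4.404
ATTRIBUTION_FACTOR = 0.618
SMR_WEIGHT = 0.618


@dataclass(frozen=True)
class CodeCounts:
    """Death/bearer counts for one predot code, split by injury multiplicity."""

    predot: str
    d1: int  # deaths among single-injury bearers
    t1: int  # single-injury bearers
    d2: int  # deaths among multiple-injury bearers
    t2: int  # multiple-injury bearers

    def __post_init__(self) -> None:
        if not (0 <= self.d1 <= self.t1 and 0 <= self.d2 <= self.t2):
            raise ValueError(f"inconsistent counts for {self.predot}: {self}")


@dataclass(frozen=True)
class WMDPEntry:
    predot: str
    counts: CodeCounts
    smr: float | None  # D1/T1, None when T1 == 0
    mmr: float | None  # D2/T2, None when T2 == 0
    tdp_top: tuple[float, ...]  # up to three worst TDP values, descending
    pmr_m: float | None  # median PMR of bearers; set when no deaths observed
    wmdp: float

    @property
    def n_u(self) -> int:
        return len(self.tdp_top)

    def __post_init__(self) -> None:
        if self.wmdp < 0:
            raise ValueError(f"negative wmdp for {self.predot}")
        if len(self.tdp_top) > 3:
            raise ValueError("tdp_top holds at most three values")


@dataclass(frozen=True)
class WMDPConfig:
    """Tunables of the derivation.

    ``attribution_constant`` defaults to ``mean_injuries * attribution_factor``
    (= 2.721672 with the packaged defaults); pass an explicit value or use
    :meth:`from_cohort` to recompute the mean from data. ``output_transform``
    is a monotone hook applied to the final score (identity by default).
    """

    mean_injuries: float = MEAN_INJURIES_PER_PATIENT
    attribution_factor: float = ATTRIBUTION_FACTOR
    attribution_constant: float | None = None
    pmr_base: float = PMR_BASE
    pmr_slope: float = PMR_SLOPE
    smr_weight: float = SMR_WEIGHT
    output_transform: Callable[[float], float] = field(default=lambda x: x)

    def __post_init__(self) -> None:
        if not 0 < self.smr_weight <= 1:
            raise ValueError("smr_weight must be in (0, 1]")
        for name in ("mean_injuries", "attribution_factor", "pmr_base", "pmr_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.attribution_constant is not None and self.attribution_constant <= 0:
            raise ValueError("attribution_constant must be positive")

    @property
    def resolved_attribution(self) -> float:
        if self.attribution_constant is not None:
            return self.attribution_constant
        return self.mean_injuries * self.attribution_factor

    @classmethod
    def from_cohort(cls, cohort: Sequence[PatientRecord], **kwargs) -> "WMDPConfig":
        """Config whose attribution constant uses the cohort's own mean number
        of distinct injuries per patient."""
        mean_inj = float(np.mean([len({i.predot for i in p.injuries})
                                  for p in cohort]))
        return cls(mean_injuries=mean_inj, **kwargs)


def pmr(age: float, base: float = PMR_BASE, slope: float = PMR_SLOPE) -> float:
    """Possible mortality rate at a given age: ``base * exp(slope * age)``."""
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    return base * math.exp(slope * age)


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted median: smallest value where the normalized cumulative weight
    reaches 0.5 (so an exact 0.5 hit returns the lower of the two middle
    candidates)."""
    if len(values) != len(weights) or not values:
        raise ValueError("values and weights must be nonempty and aligned")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    total = float(sum(weights))
    if total <= 0:
        raise ValueError("weights must not all be zero")
    order = sorted(range(len(values)), key=lambda i: values[i])
    cum = 0.0
    for i in order:
        cum += weights[i] / total
        if cum >= 0.5 - 1e-12:
            return float(values[i])
    return float(values[order[-1]])  # numerical safety net


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def _injury_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per (patient, distinct predot), with outcome and multiplicity."""
    rows = []
    for p in cohort:
        codes = {i.predot for i in p.injuries}
        multi = len(codes) > 1
        died = int(p.died)
        for code in codes:
            rows.append((p.patient_id, code, died, multi, p.age))
    return pd.DataFrame(rows, columns=["patient_id", "predot", "died", "multi", "age"])


def tabulate_code_counts(cohort: Sequence[PatientRecord]) -> list[CodeCounts]:
    """Per-code D1/T1/D2/T2 counts over a cohort.

    A patient with k distinct codes contributes to k entries; duplicate
    identical codes within one patient count once. Single/multiple status is
    by distinct-code count.
    """
    if not cohort:
        raise ValueError("empty cohort")
    df = _injury_frame(cohort)
    grp = df.groupby("predot", sort=True)
    t2 = grp["multi"].sum()
    t1 = grp.size() - t2
    d1 = df[~df["multi"]].groupby("predot")["died"].sum().reindex(t1.index, fill_value=0)
    d2 = df[df["multi"]].groupby("predot")["died"].sum().reindex(t1.index, fill_value=0)
    return [CodeCounts(predot=code, d1=int(d1[code]), t1=int(t1[code]),
                       d2=int(d2[code]), t2=int(t2[code]))
            for code in t1.index]


def tdp_values(cohort: Sequence[PatientRecord], predot: str,
               config: WMDPConfig | None = None) -> list[float]:
    """Per-patient traumatic death probabilities for one code, descending.

    Each multiple-injury bearer contributes its death indicator divided by
    the attribution constant; codes absent from multi-injury patients yield
    an empty list.
    """
    cfg = config or WMDPConfig()
    k = cfg.resolved_attribution
    vals = []
    for p in cohort:
        codes = {i.predot for i in p.injuries}
        if predot in codes and len(codes) > 1:
            vals.append((1.0 if p.died else 0.0) / k)
    return sorted(vals, reverse=True)


# ---------------------------------------------------------------------------
# Derivation
# ---------------------------------------------------------------------------


def _entry_from_counts(predot: str, counts: CodeCounts, pmr_median: float,
                       cfg: WMDPConfig) -> WMDPEntry:
    k = cfg.resolved_attribution
    smr = counts.d1 / counts.t1 if counts.t1 > 0 else None
    mmr = counts.d2 / counts.t2 if counts.t2 > 0 else None
    # per-patient TDP values are died/k or 0, so the top three follow from counts
    n_u = min(3, counts.t2)
    n_dead = min(3, counts.d2)
    tdp_top = tuple([1.0 / k] * n_dead + [0.0] * (n_u - n_dead))

    candidates: list[float] = []
    weights: list[float] = []
    if smr is not None:
        candidates.append(smr)
        weights.append(cfg.smr_weight)
    if n_u:
        candidates.extend(tdp_top)
        weights.extend([(1.0 - cfg.smr_weight) / n_u] * n_u)
    if smr is None and n_u:
        weights = [1.0 / n_u] * n_u  # renormalize when SMR is absent

    pmr_m = None
    if all(c == 0.0 for c in candidates):
        pmr_m = pmr_median
        score = pmr_m
    else:
        score = weighted_median(candidates, weights)
    return WMDPEntry(predot=predot, counts=counts, smr=smr, mmr=mmr,
                     tdp_top=tdp_top, pmr_m=pmr_m,
                     wmdp=cfg.output_transform(score))


def derive_wmdp(cohort: Sequence[PatientRecord],
                config: WMDPConfig | None = None) -> list[WMDPEntry]:
    """Derive the WMDP table from a (derivation) cohort.

    Deterministic: identical cohorts in any row order yield identical tables,
    sorted by predot code.
    """
    if not cohort:
        raise ValueError("empty cohort")
    cfg = config or WMDPConfig()
    counts = {c.predot: c for c in tabulate_code_counts(cohort)}

    ages: dict[str, list[float]] = {}
    for p in cohort:
        for code in {i.predot for i in p.injuries}:
            ages.setdefault(code, []).append(p.age)

    entries = []
    for code in sorted(counts):
        pmr_median = float(median(pmr(a, cfg.pmr_base, cfg.pmr_slope)
                                  for a in ages[code]))
        entries.append(_entry_from_counts(code, counts[code], pmr_median, cfg))
    return entries


# ---------------------------------------------------------------------------
# Table I/O (TSV contract between derive-wmdp and score)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["predot", "D1", "T1", "D2", "T2", "smr", "mmr", "n_u",
                  "pmr_m", "wmdp"]


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def write_wmdp_table(entries: Sequence[WMDPEntry], path) -> None:
    """Write the WMDP table as TSV (round-trips with :func:`read_wmdp_table`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TABLE_COLUMNS)
        for e in entries:
            writer.writerow([
                e.predot, e.counts.d1, e.counts.t1, e.counts.d2, e.counts.t2,
                _fmt(e.smr), _fmt(e.mmr), e.n_u, _fmt(e.pmr_m), repr(float(e.wmdp)),
            ])


def read_wmdp_table(path, config: WMDPConfig | None = None) -> list[WMDPEntry]:
    """Read a WMDP TSV written by :func:`write_wmdp_table`.

    Duplicate predot rows or missing columns are schema errors. Under the
    canonical attribution rule the top TDP values are ``min(3, D2)`` copies of
    ``1/attribution_constant`` padded with zeros to ``n_u``, so ``tdp_top`` is
    reconstructed from the stored counts and ``config`` (packaged defaults
    when omitted) and the round trip is an identity.
    """
    cfg = config or WMDPConfig()
    k = cfg.resolved_attribution
    entries: list[WMDPEntry] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TABLE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            code = row["predot"]
            if code in seen:
                raise ValueError(f"{path}: duplicate predot {code!r}")
            seen.add(code)
            counts = CodeCounts(predot=code, d1=int(row["D1"]), t1=int(row["T1"]),
                                d2=int(row["D2"]), t2=int(row["T2"]))
            n_u = int(row["n_u"])
            n_dead = min(3, counts.d2)
            tdp_top = tuple([1.0 / k] * n_dead + [0.0] * (n_u - n_dead))
            entries.append(WMDPEntry(
                predot=code, counts=counts,
                smr=float(row["smr"]) if row["smr"] else None,
                mmr=float(row["mmr"]) if row["mmr"] else None,
                tdp_top=tdp_top,
                pmr_m=float(row["pmr_m"]) if row["pmr_m"] else None,
                wmdp=float(row["wmdp"]),
            ))
    return entries


def wmdp_lookup(entries: Sequence[WMDPEntry]) -> dict[str, float]:
    """predot -> wmdp mapping used by the scoring module."""
    return {e.predot: e.wmdp for e in entries}
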