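"""Discrimination, calibration and information-criterion model comparison.

Implements the evaluation harness used to compare risk models on a common
validation cohort: Mann-Whitney AUC, the Hosmer-Lemeshow chi-square over risk
deciles, AIC from the validation log-likelihood, bias-corrected percentile
bootstrap confidence intervals, binned calibration tables with exact binomial
intervals, and a per-body-region stratified comparison report.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .cohort import PatientRecord, ais_to_iss_region

logger = logging.getLogger("trimp")


@dataclass(frozen=True)
class EvaluationReport:
    """One model x stratum row of the comparison table."""

    model: str
    stratum: str  # "all" or body region "1".."6"
    n: int
    auc: float
    auc_ci: tuple[float, float] | None
    hl: float
    hl_ci: tuple[float, float] | None
    aic: float
    log_likelihood: float

    def __post_init__(self) -> None:
        auc_ok = math.isnan(self.auc) or 0.0 <= self.auc <= 1.0
        if not (auc_ok and self.hl >= 0.0 and self.n > 0):
            raise ValueError(f"invalid report row: {self}")


@dataclass(frozen=True)
class CalibrationBin:
    midpoint: float  # predicted-survival bin midpoint
    n: int
    observed: float | None  # observed survival rate, None when empty
    ci: tuple[float, float] | None  # exact binomial 95% CI


@dataclass(frozen=True)
class CalibrationTable:
    bins: tuple[CalibrationBin, ...]
    n_total: int

    def __post_init__(self) -> None:
        if sum(b.n for b in self.bins) != self.n_total:
            raise ValueError("calibration bins must conserve n")


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------


def auc(scores: Sequence[float], outcomes: Sequence[int | bool]) -> float:
    """Mann-Whitney concordance: P(score_event > score_nonevent) + half ties."""
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("AUC requires both outcome classes")
    return float(roc_auc_score(y, s))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def hosmer_lemeshow(p_death: Sequence[float], outcomes: Sequence[int | bool],
                    g: int = 10) -> float:
    """Hosmer-Lemeshow chi-square over ``g`` equal-count risk groups.

    Groups are deciles of predicted death probability; each contributes
    ``(O - E)^2 / (E * (1 - E/n_g))`` where O and E are observed and expected
    deaths. Groups with zero expected variance (all-0 or all-1 predictions)
    are merged into their neighbor, with a log note.
    """
    p = np.asarray(p_death, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if g < 2:
        raise ValueError("need at least two groups")
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]
    edges = (np.arange(1, g + 1) * len(p)) // g
    groups = []
    start = 0
    for stop in edges:
        if stop > start:
            groups.append((p[start:stop], y[start:stop]))
        start = stop

    merged: list[tuple[np.ndarray, np.ndarray]] = []
    for pg, yg in groups:
        e = pg.sum()
        if e <= 0 or e >= len(pg):  # zero-variance group
            if merged:
                logger.info("Hosmer-Lemeshow: merging a zero-variance risk "
                            "group into its neighbor")
                prev_p, prev_y = merged.pop()
                merged.append((np.concatenate([prev_p, pg]),
                               np.concatenate([prev_y, yg])))
            else:
                merged.append((pg, yg))
        else:
            merged.append((pg, yg))

    stat = 0.0
    for pg, yg in merged:
        n_g = len(pg)
        e = float(pg.sum())
        o = float(yg.sum())
        denom = e * (1.0 - e / n_g)
        if denom <= 0:
            continue  # a merged block can still be degenerate; contributes 0
        stat += (o - e) ** 2 / denom
    return float(stat)


def aic(log_likelihood: float, k: int) -> float:
    """Akaike information criterion: ``2k - 2 lnL``."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return 2.0 * k - 2.0 * log_likelihood


def binomial_log_likelihood(p_death: Sequence[float],
                            outcomes: Sequence[int | bool],
                            eps: float = 1e-12) -> float:
    """Bernoulli log-likelihood of outcomes under predicted probabilities."""
    p = np.clip(np.asarray(p_death, dtype=float), eps, 1.0 - eps)
    y = np.asarray(outcomes, dtype=int)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def calibration_table(p_survival: Sequence[float],
                      outcomes: Sequence[int | bool],
                      bins: int = 10, scheme: str = "quantile",
                      ) -> CalibrationTable:
    """Binned observed-vs-predicted survival with Clopper-Pearson 95% CIs.

    ``outcomes`` are death indicators; observed survival per bin is compared
    with the bin's mean predicted survival (its midpoint). ``scheme`` is
    ``"quantile"`` (equal-count, the default) or ``"width"`` (equal-width over
    [0, 1]). Empty bins are emitted with ``n = 0`` and no interval.
    """
    p = np.asarray(p_survival, dtype=float)
    y = 1 - np.asarray(outcomes, dtype=int)  # survival indicator
    if len(p) == 0:
        return CalibrationTable(bins=(), n_total=0)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if scheme == "width":
        edges = np.linspace(0, 1, bins + 1)
    elif scheme == "quantile":
        edges = np.unique(np.quantile(p, np.linspace(0, 1, bins + 1)))
        if len(edges) < 2:
            edges = np.array([edges[0], edges[0]])
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)

    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            rows.append(CalibrationBin(
                midpoint=float((edges[b] + edges[b + 1]) / 2), n=0,
                observed=None, ci=None))
            continue
        surv = int(y[mask].sum())
        lo, hi = proportion_confint(surv, n, alpha=0.05, method="beta")
        rows.append(CalibrationBin(
            midpoint=float(p[mask].mean()), n=n,
            observed=surv / n, ci=(float(lo), float(hi))))
    return CalibrationTable(bins=tuple(rows), n_total=len(p))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(statistic: Callable[[np.ndarray], float],
                 data: Sequence, B: int = 1000, seed: int = 0,
                 alpha: float = 0.05,
                 max_failures: float = 0.01) -> tuple[float, float]:
    """Bias-corrected percentile bootstrap interval.

    ``data`` is resampled at the patient level with replacement ``B`` times;
    the bias-correction constant z0 comes from the proportion of resample
    statistics below the point estimate. Resamples on which the statistic
    fails (e.g. a single-class AUC draw) are skipped, up to ``max_failures``
    of B.
    """
    if B < 100:
        raise ValueError("at least 100 bootstrap replications required")
    arr = np.asarray(data)
    n = len(arr)
    rng = np.random.default_rng(seed)
    point = float(statistic(arr))

    stats, failures = [], 0
    for _ in range(B):
        sample = arr[rng.integers(0, n, size=n)]
        try:
            stats.append(float(statistic(sample)))
        except (ValueError, ZeroDivisionError):
            failures += 1
    if failures > max_failures * B:
        raise ValueError(
            f"statistic failed on {failures}/{B} bootstrap resamples")
    theta = np.sort(np.asarray(stats))
    if theta[0] == theta[-1]:
        return (float(theta[0]), float(theta[0]))  # degenerate: no variability

    prop_below = np.mean(theta < point)
    prop_below = min(max(prop_below, 1.0 / (len(theta) + 1)),
                     len(theta) / (len(theta) + 1.0))
    z0 = norm.ppf(prop_below)
    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    a_lo = norm.cdf(2 * z0 + z_lo)
    a_hi = norm.cdf(2 * z0 + z_hi)
    return (float(np.quantile(theta, a_lo)), float(np.quantile(theta, a_hi)))


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


def worst_injury_region(patient: PatientRecord) -> int:
    """Body region of the patient's worst injury.

    The unified default ranks by AIS severity digit (unknown severity 9
    ranked lowest), ties broken by predot code, so strata align across models.
    """
    def key(inj):
        sev = inj.severity if inj.severity != 9 else 0
        return (-sev, inj.predot)

    worst = sorted(patient.injuries, key=key)[0]
    return ais_to_iss_region(worst.predot)


def _default_k(model_name: str) -> int:
    # published-coefficient counts: 8 for the two TRISS logistic sets,
    # 20 (intercept + 19 slopes) otherwise
    return 8 if "triss" in model_name.lower() else 20


def compare_models(predictions_by_model: Mapping[str, Mapping[str, float]],
                   cohort: Sequence[PatientRecord],
                   B: int = 1000, seed: int = 0,
                   k_by_model: Mapping[str, int] | None = None,
                   ) -> list[EvaluationReport]:
    """Aligned evaluation of several models on one cohort.

    ``predictions_by_model`` maps model name to a ``patient_id -> p_death``
    mapping; every model must cover exactly the cohort's patients. Each model
    is reported overall and per worst-injury body region: AUC and HL with
    bias-corrected bootstrap CIs, and AIC from the validation log-likelihood.
    Strata where a metric is undefined (single outcome class) report that
    metric as NaN. Output is sorted by (model, stratum) so it is invariant to
    patient and model ordering.
    """
    ids = [p.patient_id for p in cohort]
    id_set = set(ids)
    for name, preds in predictions_by_model.items():
        if set(preds) != id_set:
            raise ValueError(f"model {name!r} predictions are misaligned "
                             "with the cohort patient set")
    if len(predictions_by_model) < 2:
        raise ValueError("at least two models required")
    ks = dict(k_by_model or {})

    base = pd.DataFrame({
        "patient_id": ids,
        "died": [int(p.died) for p in cohort],
        "region": [worst_injury_region(p) for p in cohort],
    }).sort_values("patient_id", kind="stable").reset_index(drop=True)

    reports = []
    for name in sorted(predictions_by_model):
        preds = predictions_by_model[name]
        df = base.assign(p_death=[preds[i] for i in base["patient_id"]])
        k = ks.get(name, _default_k(name))
        for stratum in ["all"] + [str(r) for r in range(1, 7)]:
            sub = df if stratum == "all" else df[df["region"] == int(stratum)]
            if len(sub) == 0:
                continue
            reports.append(_evaluate_stratum(name, stratum, sub, k, B, seed))
    return reports


def _evaluate_stratum(name: str, stratum: str, sub: pd.DataFrame, k: int,
                      B: int, seed: int) -> EvaluationReport:
    p = sub["p_death"].to_numpy()
    y = sub["died"].to_numpy()
    lnl = binomial_log_likelihood(p, y)
    data = np.column_stack([p, y])
    # a stable derived stream per stratum, shared across models (paired
    # resamples), so identical predictions yield identical report rows
    sub_seed = (zlib.crc32(stratum.encode()) ^ (seed * 2654435761)) % (2 ** 31 - 2)

    if y.min() == y.max():
        # single outcome class: discrimination is undefined in this stratum
        return EvaluationReport(model=name, stratum=stratum, n=len(sub),
                                auc=math.nan, auc_ci=None,
                                hl=hosmer_lemeshow(p, y), hl_ci=None,
                                aic=aic(lnl, k), log_likelihood=lnl)

    auc_point = auc(p, y)
    hl_point = hosmer_lemeshow(p, y)

    def _ci(stat, offset):
        # small strata can resample a single outcome class; report no
        # interval rather than failing the whole comparison
        try:
            return bootstrap_ci(stat, data, B=B, seed=sub_seed + offset,
                                max_failures=0.25)
        except ValueError:
            logger.info("bootstrap interval unavailable for %s stratum %s",
                        name, stratum)
            return None

    auc_ci = _ci(lambda d: auc(d[:, 0], d[:, 1]), 0)
    hl_ci = _ci(lambda d: hosmer_lemeshow(d[:, 0], d[:, 1]), 1)
    return EvaluationReport(model=name, stratum=stratum, n=len(sub),
                            auc=auc_point, auc_ci=auc_ci, hl=hl_point,
                            hl_ci=hl_ci, aic=aic(lnl, k), log_likelihood=lnl)


def reports_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Flatten evaluation reports into a DataFrame for display or export."""
    return pd.DataFrame([{
        "model": r.model, "stratum": r.stratum, "n": r.n,
        "auc": r.auc,
        "auc_lo": r.auc_ci[0] if r.auc_ci else None,
        "auc_hi": r.auc_ci[1] if r.auc_ci else None,
        "hl": r.hl,
        "hl_lo": r.hl_ci[0] if r.hl_ci else None,
        "hl_hi": r.hl_ci[1] if r.hl_ci else None,
        "aic": r.aic, "log_likelihood": r.log_likelihood,
    } for r in reports])
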