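"""Beta cell function endpoints.

Per-participant clinical endpoints derived from visit series: percent
change of 2 h stimulated C-peptide AUC from baseline, the decline slope
by truncated linear regression (visits after the series first reaches
its floor are excluded so a run of floor values does not attenuate the
slope), the insulin-dose-adjusted HbA1c (IDAA1c = HbA1c % + 4 x insulin
dose in U kg-1 day-1), partial-remission durations under either the
C-peptide rule (AUC >= 0.2 nmol/l) or the IDAA1c rule (<= 9), and the
Jenks natural-breaks two-class split of remission durations.

Remission durations use the last-compliant-visit convention: the
duration is the time of the last visit at which the criterion holds
before its first violation, 0 if violated at the first post-baseline
assessment, and censored when the criterion still holds at the final
visit.  Values exactly at the threshold count as in remission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_data_model import ClinicalCourse, Thresholds, ValidationError


@dataclass
class EndpointRecord:
    participant_id: str
    arm: str
    pct_change_by_visit: dict[float, float] = field(default_factory=dict)
    decline_slope: float = float("nan")      # nmol/l per year
    remission_months: float = float("nan")
    remission_censored: bool = False
    idaa1c_by_visit: dict[float, float] = field(default_factory=dict)
    baseline_auc: float = float("nan")


def percent_change_auc(course: ClinicalCourse) -> dict[float, float]:
    """100 * (AUC_t - AUC_0) / AUC_0 at every post-baseline visit."""
    auc0 = course.baseline_auc()
    if auc0 <= 0:
        raise ValidationError(
            f"participant {course.participant_id!r}: baseline AUC must be > 0")
    out: dict[float, float] = {}
    for t, v in zip(course.visit_times_months, course.cpeptide_auc_nmol_l):
        if v is None:
            continue
        out[t] = 100.0 * (v - auc0) / auc0
    return out


def cpeptide_slope(course: ClinicalCourse, floor: float = 0.0,
                   truncate: bool = True) -> float:
    """OLS slope of C-peptide AUC (nmol/l) against time (years).

    With ``truncate`` (the default), visits after the first one at which
    the AUC reaches ``floor`` are excluded; the floor-reaching visit
    itself is kept.
    """
    if course.cpeptide_auc_nmol_l is None:
        raise ValidationError(
            f"participant {course.participant_id!r}: no C-peptide series")
    pairs = [(t, v) for t, v in zip(course.visit_times_months,
                                    course.cpeptide_auc_nmol_l)
             if v is not None]
    if truncate:
        kept = []
        for t, v in pairs:
            kept.append((t, v))
            if v <= floor:
                break
        pairs = kept
    if len(pairs) < 2:
        raise ValidationError(
            f"participant {course.participant_id!r}: fewer than 2 usable visits")
    t = np.array([p[0] for p in pairs]) / 12.0
    y = np.array([p[1] for p in pairs])
    if np.ptp(t) == 0:
        raise ValidationError("degenerate visit times")
    return float(np.polyfit(t, y, 1)[0])


def idaa1c(hba1c_percent: float, insulin_u_per_kg_day: float) -> float:
    """Insulin-dose-adjusted HbA1c: HbA1c(%) + 4 x dose (U kg-1 day-1)."""
    if hba1c_percent < 0 or insulin_u_per_kg_day < 0:
        raise ValidationError("IDAA1c inputs must be non-negative")
    return hba1c_percent + 4.0 * insulin_u_per_kg_day


def idaa1c_series(course: ClinicalCourse) -> dict[float, float]:
    if course.hba1c_percent is None or course.insulin_u_per_kg_day is None:
        raise ValidationError(
            f"participant {course.participant_id!r}: HbA1c/insulin series missing")
    out: dict[float, float] = {}
    for t, h, d in zip(course.visit_times_months, course.hba1c_percent,
                       course.insulin_u_per_kg_day):
        if h is None or d is None:
            continue
        out[t] = idaa1c(h, d)
    return out


def remission_duration(course: ClinicalCourse, mode: str,
                       th: Thresholds) -> tuple[float, bool]:
    """(months in remission, censored) under the chosen criterion."""
    if mode == "cpeptide":
        if course.cpeptide_auc_nmol_l is None:
            raise ValidationError(
                f"participant {course.participant_id!r}: no C-peptide series")
        series = [(t, v) for t, v in zip(course.visit_times_months,
                                         course.cpeptide_auc_nmol_l)
                  if v is not None]
        ok = [v >= th.cpeptide_floor_nmol_l for _, v in series]
    elif mode == "idaa1c":
        s = idaa1c_series(course)
        series = sorted(s.items())
        ok = [v <= th.idaa1c_max for _, v in series]
    else:
        raise ValidationError(f"unknown remission mode {mode!r}")
    if not series:
        raise ValidationError(
            f"participant {course.participant_id!r}: empty series")
    last_ok = 0.0
    for (t, _), good in zip(series, ok):
        if not good:
            return last_ok, False
        last_ok = t
    return last_ok, True


def compute_endpoints(courses: list[ClinicalCourse], th: Thresholds,
                      remission_mode: str = "cpeptide",
                      ) -> list[EndpointRecord]:
    """All endpoints per participant (series permitting)."""
    records = []
    for c in courses:
        rec = EndpointRecord(participant_id=c.participant_id, arm=c.arm)
        if c.cpeptide_auc_nmol_l is not None:
            rec.baseline_auc = c.baseline_auc()
            rec.pct_change_by_visit = percent_change_auc(c)
            rec.decline_slope = cpeptide_slope(c, floor=0.0)
        try:
            rec.remission_months, rec.remission_censored = remission_duration(
                c, remission_mode, th)
        except ValidationError:
            pass
        try:
            rec.idaa1c_by_visit = idaa1c_series(c)
        except ValidationError:
            pass
        records.append(rec)
    return records


def jenks_two_class(values) -> tuple[float, list[int]]:
    """Two-class Jenks natural breaks (exact, by exhaustive split).

    Splits the sorted values into two contiguous classes minimising the
    total within-class sum of squared deviations from the class means.
    Returns the break value (largest member of the lower class) and
    labels (0 = lower class, 1 = upper class) in input order.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValidationError("need >= 2 distinct values")
    order = np.argsort(v, kind="stable")
    s = v[order]
    best_cost, best_split = np.inf, 1
    for split in range(1, v.size):
        lo, hi = s[:split], s[split:]
        cost = (((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
        if cost < best_cost - 1e-12:
            best_cost, best_split = cost, split
    break_value = float(s[best_split - 1])
    labels = np.empty(v.size, dtype=int)
    labels[order[:best_split]] = 0
    labels[order[best_split:]] = 1
    return break_value, labels.tolist()
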