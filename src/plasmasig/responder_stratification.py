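"""Residual-based responder selection and placebo matching.

The placebo arm defines reference regression lines of outcome on
baseline index: one line per post-baseline timepoint (outcome = percent
change of stimulated C-peptide AUC) plus one line for the decline
slope.  A treated participant is a responder when their outcome residual
exceeds ``responder_sd_timepoint`` placebo residual SDs above the line
at >= ``responder_min_timepoints`` timepoints AND exceeds
``responder_sd_slope`` SDs above the slope line — "above" meaning
better-preserved C-peptide.  Selected responders are compared against
placebo participants matched for baseline index that sit at or below the
slope reference line (rapid progressors), matched greedily by nearest
index without replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clinical_endpoints import EndpointRecord
from .inflammatory_index import IndexScore
from .io_data_model import SampleTable, Thresholds, ValidationError
from .survival_association import ols_line, _index_by_participant

SLOPE_LINE = "slope"


@dataclass
class ReferenceLine:
    timepoint: float | str   # months, or "slope"
    intercept: float
    slope: float
    residual_sd: float
    n: int


@dataclass
class ResponderSet:
    responders: list[str]
    matched_placebos: list[str]
    criteria_log: dict[str, dict[str, float]] = field(default_factory=dict)


def fit_reference_lines(placebo_index: dict[str, float],
                        placebo_endpoints: list[EndpointRecord],
                        ) -> list[ReferenceLine]:
    """Placebo OLS lines per timepoint and for the decline slope.

    residual_sd is the SD (n - 2 denominator) of placebo residuals about
    each line.  Lines with fewer than 3 placebo points are omitted.
    """
    lines: list[ReferenceLine] = []
    timepoints = sorted({t for e in placebo_endpoints
                         for t in e.pct_change_by_visit if t > 0})
    for t in timepoints:
        pairs = [(placebo_index[e.participant_id], e.pct_change_by_visit[t])
                 for e in placebo_endpoints
                 if e.participant_id in placebo_index
                 and t in e.pct_change_by_visit]
        if len(pairs) < 3:
            continue
        fit = ols_line([p[0] for p in pairs], [p[1] for p in pairs])
        lines.append(ReferenceLine(t, fit["intercept"], fit["slope"],
                                   fit["residual_sd"], fit["n"]))
    pairs = [(placebo_index[e.participant_id], e.decline_slope)
             for e in placebo_endpoints
             if e.participant_id in placebo_index
             and np.isfinite(e.decline_slope)]
    if len(pairs) >= 3:
        fit = ols_line([p[0] for p in pairs], [p[1] for p in pairs])
        lines.append(ReferenceLine(SLOPE_LINE, fit["intercept"], fit["slope"],
                                   fit["residual_sd"], fit["n"]))
    return lines


def _residual_sd_units(line: ReferenceLine, index: float,
                       outcome: float) -> float:
    if line.residual_sd <= 0:
        raise ValidationError(
            f"degenerate residual SD on reference line {line.timepoint!r}")
    predicted = line.intercept + line.slope * index
    return (outcome - predicted) / line.residual_sd


def select_responders(treated_index: dict[str, float],
                      treated_endpoints: list[EndpointRecord],
                      lines: list[ReferenceLine], th: Thresholds,
                      ) -> tuple[list[str], dict[str, dict[str, float]]]:
    """Treated participants passing both residual criteria.

    Criterion 1: residual > th.responder_sd_timepoint SD units at
    >= th.responder_min_timepoints timepoint lines (missing visits do
    not count either way).  Criterion 2: residual >
    th.responder_sd_slope SD units above the decline-slope line.
    Returns (sorted participant ids, per-participant residual log).
    """
    tp_lines = [l for l in lines if l.timepoint != SLOPE_LINE]
    slope_lines = [l for l in lines if l.timepoint == SLOPE_LINE]
    if len(tp_lines) < th.responder_min_timepoints or not slope_lines:
        raise ValidationError(
            "reference lines must include >= responder_min_timepoints "
            "timepoints and the slope line")
    slope_line = slope_lines[0]
    selected = []
    log: dict[str, dict[str, float]] = {}
    for e in treated_endpoints:
        pid = e.participant_id
        if pid not in treated_index:
            continue
        x = treated_index[pid]
        record: dict[str, float] = {}
        n_exceed = 0
        for line in tp_lines:
            t = float(line.timepoint)
            if t not in e.pct_change_by_visit:
                continue
            z = _residual_sd_units(line, x, e.pct_change_by_visit[t])
            record[f"tp_{t:g}"] = z
            if z > th.responder_sd_timepoint:
                n_exceed += 1
        ok_slope = False
        if np.isfinite(e.decline_slope):
            z = _residual_sd_units(slope_line, x, e.decline_slope)
            record[SLOPE_LINE] = z
            ok_slope = z > th.responder_sd_slope
        log[pid] = record
        if n_exceed >= th.responder_min_timepoints and ok_slope:
            selected.append(pid)
    return sorted(selected), log


def match_placebos(selected_index: dict[str, float],
                   placebo_index: dict[str, float],
                   placebo_endpoints: list[EndpointRecord],
                   lines: list[ReferenceLine],
                   n_matches: int | None = None) -> list[str]:
    """Nearest-index matching among rapidly progressing placebos.

    Eligible placebos sit at or below the decline-slope reference line
    (residual <= 0).  Matching is without replacement and minimises the
    total |index difference| over matched pairs (optimal assignment);
    when ``n_matches`` is smaller than the number of selected treated
    participants, the closest pairs are kept.
    """
    slope_lines = [l for l in lines if l.timepoint == SLOPE_LINE]
    if not slope_lines:
        raise ValidationError("slope reference line required for matching")
    slope_line = slope_lines[0]
    eligible = []
    for e in placebo_endpoints:
        pid = e.participant_id
        if pid not in placebo_index or not np.isfinite(e.decline_slope):
            continue
        resid = (e.decline_slope
                 - (slope_line.intercept
                    + slope_line.slope * placebo_index[pid]))
        if resid <= 0:
            eligible.append(pid)
    if not eligible:
        raise ValidationError("no eligible placebo below the slope line")
    if n_matches is None:
        n_matches = len(selected_index)
    treated_ids = sorted(selected_index)
    pool = sorted(set(eligible))
    if not treated_ids:
        return []
    cost = np.array([[abs(selected_index[t] - placebo_index[p])
                      for p in pool] for t in treated_ids])
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted(zip(cost[rows, cols], (pool[c] for c in cols)),
                   key=lambda w: (w[0], w[1]))
    return sorted(p for _, p in pairs[:n_matches])


def stratify(scores: list[IndexScore], endpoints: list[EndpointRecord],
             samples: SampleTable, th: Thresholds) -> ResponderSet:
    """Full stratification: reference lines, selection, matching."""
    index = _index_by_participant(scores, samples)
    placebo = [e for e in endpoints if e.arm == "placebo"]
    treated = [e for e in endpoints if e.arm == "treated"]
    lines = fit_reference_lines(index, placebo)
    responders, log = select_responders(index, treated, lines, th)
    matched = match_placebos({p: index[p] for p in responders},
                             index, placebo, lines)
    return ResponderSet(responders=responders, matched_placebos=matched,
                        criteria_log=log)
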