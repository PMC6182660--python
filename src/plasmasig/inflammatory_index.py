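"""Composite inflammatory index scoring, cohort comparison, ROC.

The inflammatory index contrasts the mean induced expression of an
inflammatory probe set against a regulatory probe set.  On the log2
scale the "ratio of average signal intensities" becomes a difference of
set means — the log of a ratio of geometric means.  By default each
probe is centered across samples first, which puts the scores on a
negative-to-positive scale around zero and makes them invariant to
per-probe intensity offsets; the uncentered difference is available as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_data_model import (
    ExpressionMatrix,
    GeneSetPartition,
    SampleTable,
    ValidationError,
)


@dataclass
class IndexScore:
    sample_id: str
    value: float


def compute_index(matrix: ExpressionMatrix, partition: GeneSetPartition,
                  center: bool = True) -> list[IndexScore]:
    """Per-sample inflammatory-vs-regulatory contrast on the log2 scale.

    value = mean(log2, inflammatory set) - mean(log2, regulatory set),
    after per-probe centering across samples when ``center`` is true.
    """
    pidx = matrix.probe_index()
    infl = [pidx[p] for p in sorted(partition.inflammatory_probes) if p in pidx]
    reg = [pidx[p] for p in sorted(partition.regulatory_probes) if p in pidx]
    if not infl or not reg:
        raise ValidationError(
            "partition does not intersect the matrix probes")
    values = matrix.values
    if center:
        values = values - values.mean(axis=1, keepdims=True)
    scores = values[infl, :].mean(axis=0) - values[reg, :].mean(axis=0)
    return [IndexScore(s, float(v)) for s, v in zip(matrix.sample_ids, scores)]


def scores_as_series(scores: list[IndexScore]) -> pd.Series:
    return pd.Series({s.sample_id: s.value for s in scores}, name="index")


def compare_cohort_indices(scores: list[IndexScore],
                           samples: SampleTable) -> pd.DataFrame:
    """Pairwise two-tailed unpaired t tests between cohort score means."""
    by_sample = {s.sample_id: s.value for s in scores}
    cohort_values: dict[str, np.ndarray] = {}
    for rec in samples.records:
        if rec.sample_id in by_sample:
            cohort_values.setdefault(rec.cohort, []).append(
                by_sample[rec.sample_id])
    usable = {c: np.asarray(v, dtype=float)
              for c, v in cohort_values.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValidationError("need >= 2 cohorts with >= 2 samples")
    rows = []
    names = sorted(usable)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = usable[a], usable[b]
            t, p = stats.ttest_ind(va, vb, equal_var=False)
            rows.append({
                "cohort_a": a, "cohort_b": b,
                "mean_a": va.mean(), "se_a": va.std(ddof=1) / np.sqrt(len(va)),
                "mean_b": vb.mean(), "se_b": vb.std(ddof=1) / np.sqrt(len(vb)),
                "t": float(t), "p_value": float(p),
            })
    return pd.DataFrame(rows)


def roc_auc(scores: list[IndexScore], positive: set[str],
            ) -> tuple[float, pd.DataFrame]:
    """AUC by the rank (Mann-Whitney) formulation, ties counted 0.5.

    Returns the AUC and the ROC curve points (one row per threshold).
    """
    pos = np.array([s.value for s in scores if s.sample_id in positive])
    neg = np.array([s.value for s in scores if s.sample_id not in positive])
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be non-empty")
    # Mann-Whitney U via midranks
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    thresholds = np.concatenate(([np.inf], np.unique(combined)[::-1]))
    points = []
    for thr in thresholds:
        points.append({
            "threshold": thr,
            "tpr": float((pos >= thr).mean()),
            "fpr": float((neg >= thr).mean()),
        })
    return auc, pd.DataFrame(points)
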