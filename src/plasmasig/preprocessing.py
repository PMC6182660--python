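"""Probe filtering and baseline normalisation.

Stages applied before signature selection and network analysis: removal
of low-intensity probes (threshold form: maximum log2 intensity below a
floor; count form: the n dimmest probes by mean), retention of the most
variable probes by median absolute deviation, probe-set intersection
across platforms/cohorts, and within-participant baseline normalisation
of longitudinal trial samples.
"""

from __future__ import annotations

import numpy as np

from .io_data_model import ExpressionMatrix, SampleTable, ValidationError


def filter_low_intensity(matrix: ExpressionMatrix, max_log2: float = 4.0,
                         n_remove: int | None = None) -> ExpressionMatrix:
    """Drop dim probes.

    With ``n_remove`` given, drops exactly the ``n_remove`` probes with
    the lowest mean intensity; otherwise drops probes whose maximum log2
    value is below ``max_log2``.  Survivor order is preserved.
    """
    if matrix.n_probes == 0:
        raise ValidationError("empty matrix")
    if n_remove is not None:
        if n_remove >= matrix.n_probes:
            raise ValidationError(
                f"n_remove={n_remove} >= probe count {matrix.n_probes}")
        means = matrix.values.mean(axis=1)
        # stable tie-break: mean, then probe id
        order = sorted(range(matrix.n_probes),
                       key=lambda i: (means[i], matrix.probe_ids[i]))
        drop = set(order[:n_remove])
        keep = [p for i, p in enumerate(matrix.probe_ids) if i not in drop]
    else:
        maxima = matrix.values.max(axis=1)
        keep = [p for i, p in enumerate(matrix.probe_ids)
                if maxima[i] >= max_log2]
    return matrix.subset_probes(keep)


def probe_mad(matrix: ExpressionMatrix) -> np.ndarray:
    """Unscaled per-probe MAD: median of |x - median(x)| across samples."""
    med = np.median(matrix.values, axis=1, keepdims=True)
    return np.median(np.abs(matrix.values - med), axis=1)


def select_high_mad(matrix: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Retain the k probes with the greatest median absolute deviation.

    The MAD is unscaled (no 1.4826 consistency factor); ties are broken
    by probe-ID lexicographic order for determinism.  Survivors keep
    their original row order.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > matrix.n_probes:
        raise ValidationError(f"k={k} exceeds probe count {matrix.n_probes}")
    mads = probe_mad(matrix)
    ranked = sorted(range(matrix.n_probes),
                    key=lambda i: (-mads[i], matrix.probe_ids[i]))
    chosen = set(ranked[:k])
    keep = [p for i, p in enumerate(matrix.probe_ids) if i in chosen]
    return matrix.subset_probes(keep)


def intersect_probes(a: ExpressionMatrix, b: ExpressionMatrix) -> set[str]:
    return set(a.probe_ids) & set(b.probe_ids)


def baseline_normalize(matrix: ExpressionMatrix,
                       samples: SampleTable) -> ExpressionMatrix:
    """Subtract each participant's baseline profile from later timepoints.

    Output value = log2 intensity at the timepoint minus log2 intensity
    at the same participant's baseline (timepoint 0) sample, per probe.
    Baseline samples are excluded from the output.  Normalisation never
    crosses participants.
    """
    meta = samples.by_sample()
    baseline_col: dict[str, int] = {}
    sidx = matrix.sample_index()
    for sid, rec in meta.items():
        if sid in sidx and rec.timepoint_months == 0.0:
            baseline_col[rec.participant_id] = sidx[sid]
    out_ids, out_cols = [], []
    for sid in matrix.sample_ids:
        rec = meta.get(sid)
        if rec is None or rec.timepoint_months == 0.0:
            continue
        base = baseline_col.get(rec.participant_id)
        if base is None:
            raise ValidationError(
                f"participant {rec.participant_id!r} has no baseline sample")
        out_ids.append(sid)
        out_cols.append(matrix.values[:, sidx[sid]] - matrix.values[:, base])
    values = (np.column_stack(out_cols) if out_cols
              else np.empty((matrix.n_probes, 0)))
    return ExpressionMatrix(list(matrix.probe_ids), out_ids, values)
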