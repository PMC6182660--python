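"""Discriminative-signature selection.

The composite signature is the intersection of two screens run on the
four cross-sectional cohorts:

* a regulation screen — per-probe group-mean log2 ratios with
  Welch t (pairwise) or one-way ANOVA p-values and Benjamini-Hochberg
  FDR within contrast; a probe passes at |log2 ratio| > 0.263
  (1.2-fold) and FDR < 20 %;
* an importance screen — mean decrease in Gini impurity from a seeded
  random forest classifying one cohort against the rest, thresholded
  either on an absolute Gini score or as top-k by importance.

Signature probes are then partitioned into inflammatory and regulatory
sets by the cohort in which their mean expression peaks (peaks in the
diabetic or low-HLA-risk sibling cohorts -> inflammatory; peaks in the
high-HLA-risk sibling or unrelated control cohorts -> regulatory), which
is this pipeline's automated proxy for the study's ontology curation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .io_data_model import (
    ExpressionMatrix,
    GeneSetPartition,
    SampleTable,
    Thresholds,
    ValidationError,
)

INFLAMMATORY_COHORTS = ("ROT1D", "LRS")
REGULATORY_COHORTS = ("HRS", "uHC")


@dataclass
class DifferentialResult:
    probe_id: str
    log2_ratio: float
    p_value: float
    fdr: float
    direction: str  # up | down
    contrast: str


@dataclass
class ImportanceResult:
    probe_id: str
    gini: float
    contrast: str = ""


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_induction(matrix: ExpressionMatrix, groups: dict[str, str],
                           th: Thresholds, mode: str = "pairwise",
                           ) -> list[DifferentialResult]:
    """Per-probe group contrasts with BH FDR within contrast.

    ``mode='pairwise'``: every unordered group pair, Welch's t, log2
    ratio = difference of group means (first minus second group in the
    contrast label).  ``mode='anova'``: one-way ANOVA across all groups;
    the reported ratio is the largest pairwise mean difference.
    """
    levels = sorted(set(groups.values()))
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    cols: dict[str, np.ndarray] = {}
    sidx = matrix.sample_index()
    for g in levels:
        members = [sidx[s] for s, gg in groups.items()
                   if gg == g and s in sidx]
        if len(members) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
        cols[g] = matrix.values[:, members]

    results: list[DifferentialResult] = []
    if mode == "pairwise":
        for a, b in itertools.combinations(levels, 2):
            ratio = cols[a].mean(axis=1) - cols[b].mean(axis=1)
            _, p = stats.ttest_ind(cols[a], cols[b], axis=1, equal_var=False)
            p = np.nan_to_num(p, nan=1.0)
            fdr = bh_fdr(p)
            contrast = f"{a}_vs_{b}"
            for i, probe in enumerate(matrix.probe_ids):
                results.append(DifferentialResult(
                    probe, float(ratio[i]), float(p[i]), float(fdr[i]),
                    "up" if ratio[i] >= 0 else "down", contrast))
    elif mode == "anova":
        arrays = [cols[g] for g in levels]
        _, p = stats.f_oneway(*arrays, axis=1)
        p = np.nan_to_num(p, nan=1.0)
        fdr = bh_fdr(p)
        means = np.column_stack([a.mean(axis=1) for a in arrays])
        ratio = means.max(axis=1) - means.min(axis=1)
        for i, probe in enumerate(matrix.probe_ids):
            results.append(DifferentialResult(
                probe, float(ratio[i]), float(p[i]), float(fdr[i]),
                "up", "anova"))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return results


def passes_regulation(r: DifferentialResult, th: Thresholds,
                      use_alpha: bool = False) -> bool:
    ok = abs(r.log2_ratio) > th.log2_fc and r.fdr < th.diff_fdr
    if use_alpha:
        ok = ok and r.p_value < th.diff_alpha
    return ok


def rf_importance(matrix: ExpressionMatrix, labels: dict[str, str],
                  one_vs_rest_group: str, n_trees: int = 1000,
                  seed: int = 0,
                  ensemble: str = "random_forest") -> list[ImportanceResult]:
    """Per-probe mean decrease in Gini impurity, one group vs the rest.

    Importances come from a seeded tree ensemble (feature subsampling
    sqrt(p)).  ``ensemble='extra_trees'`` swaps in extremely randomised
    trees, whose impurity importances rank large sets of correlated
    informative probes with less variance than bootstrap forests; the
    numbers are normalised to sum to one either way, so the absolute
    scale differs from other tree-ensemble tools and the top-k selection
    modes are the robust way to consume them.
    """
    y = np.array([1 if labels[s] == one_vs_rest_group else 0
                  for s in matrix.sample_ids])
    if len(np.unique(y)) < 2:
        raise ValidationError("one-vs-rest binarisation left a single class")
    if min(int((y == 1).sum()), int((y == 0).sum())) < 2:
        raise ValidationError("need >= 2 samples per class")
    cls = {"random_forest": RandomForestClassifier,
           "extra_trees": ExtraTreesClassifier}.get(ensemble)
    if cls is None:
        raise ValidationError(f"unknown ensemble {ensemble!r}")
    forest = cls(n_estimators=n_trees, max_features="sqrt",
                 random_state=seed, n_jobs=1)
    forest.fit(matrix.values.T, y)
    contrast = f"{one_vs_rest_group}_vs_rest"
    return [ImportanceResult(p, float(g), contrast)
            for p, g in zip(matrix.probe_ids, forest.feature_importances_)]


def select_signature(diff: list[DifferentialResult],
                     imp: list[ImportanceResult], th: Thresholds,
                     top_k: int | None = None,
                     top_k_per_contrast: int | None = None,
                     use_alpha: bool = False) -> list[str]:
    """Probes passing BOTH the importance and the regulation criteria.

    Importance criterion, one of: gini above ``th.gini_min`` in any
    one-vs-rest contrast (the study's absolute-cut form); membership in
    the global top-``top_k`` by maximal importance; or membership in the
    top-``top_k_per_contrast`` of any single contrast — the analog of an
    absolute cut applied within each comparison, appropriate when the
    importance scale differs from the study's tool.  Regulation
    criterion: passes the fold-change/FDR thresholds in >= 1 contrast.
    Sorted by probe ID.
    """
    regulated = {r.probe_id for r in diff if passes_regulation(r, th, use_alpha)}
    best_gini: dict[str, float] = {}
    by_contrast: dict[str, dict[str, float]] = {}
    for r in imp:
        best_gini[r.probe_id] = max(best_gini.get(r.probe_id, 0.0), r.gini)
        by_contrast.setdefault(r.contrast, {})[r.probe_id] = r.gini
    if top_k_per_contrast is not None:
        important: set[str] = set()
        for ginis in by_contrast.values():
            ranked = sorted(ginis, key=lambda p: (-ginis[p], p))
            important |= set(ranked[:top_k_per_contrast])
    elif top_k is not None:
        ranked = sorted(best_gini, key=lambda p: (-best_gini[p], p))
        important = set(ranked[:top_k])
    else:
        important = {p for p, g in best_gini.items() if g > th.gini_min}
    return sorted(regulated & important)


def partition_gene_sets(matrix: ExpressionMatrix, samples: SampleTable,
                        signature: list[str], th: Thresholds,
                        ) -> GeneSetPartition:
    """Assign each signature probe to the cohort where its mean peaks.

    Probes peaking in ROT1D or LRS are inflammatory; probes peaking in
    HRS or uHC are regulatory.
    """
    if not signature:
        raise ValidationError("empty signature")
    cohorts = INFLAMMATORY_COHORTS + REGULATORY_COHORTS
    sidx = matrix.sample_index()
    cohort_cols = {c: [sidx[s] for s in samples.samples_in_cohort(c)
                       if s in sidx] for c in cohorts}
    for c, members in cohort_cols.items():
        if not members:
            raise ValidationError(f"cohort {c} has no samples in the matrix")
    pidx = matrix.probe_index()
    infl, reg = set(), set()
    for probe in signature:
        row = matrix.values[pidx[probe], :]
        means = {c: row[cohort_cols[c]].mean() for c in cohorts}
        peak = max(sorted(means), key=lambda c: means[c])
        (infl if peak in INFLAMMATORY_COHORTS else reg).add(probe)
    if not infl or not reg:
        raise ValidationError(
            "one partition set is empty; revise selection thresholds")
    return GeneSetPartition(infl, reg)


def directional_concordance(a, b, fdr=None, fdr_max: float | None = None,
                            ) -> dict[str, float]:
    """Fraction of positions where sign(a) == sign(b).

    ``a`` is the reference vector and must contain no zeros.  When
    per-probe FDR values are supplied, a second count restricted to
    positions with fdr < fdr_max is reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.any(a == 0):
        raise ValidationError("reference vector contains zeros")
    agree = np.sign(a) == np.sign(b)
    out = {"n": int(a.size), "concordant": int(agree.sum()),
           "fraction": float(agree.mean())}
    if fdr is not None and fdr_max is not None:
        fdr = np.asarray(fdr, dtype=float)
        if fdr.shape != a.shape:
            raise ValidationError("fdr length mismatch")
        sig = agree & (fdr < fdr_max)
        out["concordant_significant"] = int(sig.sum())
        out["fraction_significant"] = float(sig.mean())
    return out
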