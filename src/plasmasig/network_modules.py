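"""Weighted co-expression network modules and subgroup discovery.

Correlation-based adjacency raised to a soft-threshold power (chosen so
the network approximates scale-free topology), topological-overlap
similarity, average-linkage module detection with a static height cut
and eigengene-based merging, module eigengenes (first principal
component of the standardised module submatrix), eigengene-trait
correlations, participant subgroup discovery by hierarchical clustering
on correlation distance, and per-subgroup clinical comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .clinical_endpoints import EndpointRecord
from .io_data_model import ExpressionMatrix, SampleTable, ValidationError

MODULE_COLOURS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue")
UNASSIGNED = "grey"


@dataclass
class NetworkConfig:
    power_candidates: tuple[int, ...] = tuple(range(1, 21))
    power: int = 12
    network_sign: str = "unsigned"      # unsigned | signed
    min_module_size: int = 30
    merge_cut: float = 0.25
    cut_height: float = 0.99            # static cut on the 1 - TOM scale
    scale_free_r2_min: float = 0.8
    n_connectivity_bins: int = 10

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValidationError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValidationError(f"unknown network sign {self.network_sign!r}")


@dataclass
class ModuleAssignment:
    labels: dict[str, str]                       # probe -> module colour
    eigengenes: pd.DataFrame = field(
        default_factory=pd.DataFrame)            # samples x modules
    module_sizes: dict[str, int] = field(default_factory=dict)

    def probes_in(self, module: str) -> list[str]:
        return [p for p, m in self.labels.items() if m == module]

    @property
    def modules(self) -> list[str]:
        return sorted({m for m in self.labels.values() if m != UNASSIGNED},
                      key=lambda m: (-self.module_sizes.get(m, 0), m))


@dataclass
class SubgroupAssignment:
    labels: dict[str, int]       # participant -> subgroup index (1..k)
    k: int
    linkage: np.ndarray | None = None


def _drop_constant_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    sd = matrix.values.std(axis=1)
    if np.any(sd == 0):
        keep = [p for p, s in zip(matrix.probe_ids, sd) if s > 0]
        warnings.warn(f"excluding {matrix.n_probes - len(keep)} constant probes")
        return matrix.subset_probes(keep)
    return matrix


def adjacency_matrix(matrix: ExpressionMatrix, power: int,
                     network_sign: str = "unsigned") -> np.ndarray:
    """Soft-thresholded correlation adjacency with zero diagonal."""
    matrix = _drop_constant_probes(matrix)
    cor = np.corrcoef(matrix.values)
    if network_sign == "unsigned":
        adj = np.abs(cor) ** power
    else:
        adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 0.0)
    return np.clip(adj, 0.0, 1.0)


def pick_soft_threshold(matrix: ExpressionMatrix,
                        config: NetworkConfig) -> tuple[pd.DataFrame, int | None]:
    """Scale-free fit R^2 and mean connectivity per candidate power.

    For each power: connectivity k_i = sum_j a_ij; the scale-free fit is
    the r^2 of log10(frequency) on log10(binned connectivity) over
    logarithmic bins.  Returns the table and the smallest power whose
    fit exceeds ``config.scale_free_r2_min`` (None when no power does).
    """
    if matrix.n_samples < 3 or matrix.n_probes < 10:
        raise ValidationError("need >= 3 samples and >= 10 probes")
    matrix = _drop_constant_probes(matrix)
    cor = np.corrcoef(matrix.values)
    np.fill_diagonal(cor, 0.0)
    rows = []
    chosen = None
    for power in config.power_candidates:
        if config.network_sign == "unsigned":
            adj = np.abs(cor) ** power
        else:
            adj = ((1.0 + cor) / 2.0) ** power
            np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        r2 = _scale_free_r2(k, config.n_connectivity_bins)
        rows.append({"power": power, "scale_free_r2": r2,
                     "mean_connectivity": float(k.mean())})
        if chosen is None and r2 > config.scale_free_r2_min:
            chosen = power
    return pd.DataFrame(rows), chosen


def _scale_free_r2(connectivity: np.ndarray, n_bins: int) -> float:
    k = connectivity[connectivity > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return 0.0
    # equal-width bins in k (frequency varies across bins)
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return 0.0
    return float(stats.linregress(xs, ys).rvalue ** 2)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij); TOM_ii = 1."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(tom_dissim: np.ndarray, config: NetworkConfig,
                   probe_ids: list[str] | None = None,
                   matrix: ExpressionMatrix | None = None,
                   ) -> ModuleAssignment:
    """Average-linkage modules from a static height cut.

    Clusters formed below ``config.cut_height`` on the dissimilarity
    scale with size >= ``min_module_size`` become modules (colour
    labels, by decreasing size); everything else is grey.  When the
    expression matrix is supplied, modules whose eigengenes correlate
    above 1 - merge_cut are merged.
    """
    d = np.asarray(tom_dissim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity must be square")
    n = d.shape[0]
    if probe_ids is None:
        probe_ids = [f"probe{i}" for i in range(n)]
    if n < config.min_module_size:
        return ModuleAssignment({p: UNASSIGNED for p in probe_ids},
                                module_sizes={})
    link = average(squareform(d, checks=False))
    flat = fcluster(link, t=config.cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(flat):
        clusters.setdefault(int(c), []).append(i)
    big = [members for members in clusters.values()
           if len(members) >= config.min_module_size]
    big.sort(key=lambda m: (-len(m), probe_ids[m[0]]))

    groups = [list(m) for m in big]
    if matrix is not None and len(groups) > 1:
        groups = _merge_by_eigengene(groups, matrix, probe_ids, config)
        groups.sort(key=lambda m: (-len(m), probe_ids[m[0]]))

    labels = {p: UNASSIGNED for p in probe_ids}
    sizes: dict[str, int] = {}
    for rank, members in enumerate(groups):
        colour = (MODULE_COLOURS[rank] if rank < len(MODULE_COLOURS)
                  else f"module{rank + 1}")
        for i in members:
            labels[probe_ids[i]] = colour
        sizes[colour] = len(members)
    assignment = ModuleAssignment(labels, module_sizes=sizes)
    if matrix is not None and sizes:
        assignment.eigengenes = module_eigengenes(matrix, assignment)
    return assignment


def _merge_by_eigengene(groups: list[list[int]], matrix: ExpressionMatrix,
                        probe_ids: list[str],
                        config: NetworkConfig) -> list[list[int]]:
    merged = True
    groups = [list(g) for g in groups]
    while merged and len(groups) > 1:
        merged = False
        eig = []
        for g in groups:
            eig.append(_first_pc(matrix.subset_probes(
                [probe_ids[i] for i in g])))
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                r = abs(float(np.corrcoef(eig[i], eig[j])[0, 1]))
                if r > 1.0 - config.merge_cut and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is not None:
            _, i, j = best
            groups[i] = groups[i] + groups[j]
            del groups[j]
            merged = True
    return groups


def _first_pc(sub: ExpressionMatrix) -> np.ndarray:
    x = sub.values
    sd = x.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise ValidationError("module of constant probes")
    x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc = vt[0]
    mean_profile = x.mean(axis=0)
    if np.corrcoef(pc, mean_profile)[0, 1] < 0:
        pc = -pc
    return pc


def module_eigengenes(matrix: ExpressionMatrix,
                      assignment: ModuleAssignment) -> pd.DataFrame:
    """First PC per module (samples x modules), unit norm, sign-oriented
    to correlate positively with the module mean expression profile."""
    data = {}
    for module in assignment.modules:
        probes = [p for p in assignment.probes_in(module)
                  if p in set(matrix.probe_ids)]
        if len(probes) < 2:
            raise ValidationError(f"module {module!r} has fewer than 2 probes")
        data[module] = _first_pc(matrix.subset_probes(probes))
    return pd.DataFrame(data, index=matrix.sample_ids)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p per module x trait (pairwise deletion)."""
    traits = traits.loc[eigengenes.index]
    rows = []
    for trait in traits.columns:
        tv = traits[trait].astype(float)
        if tv.dropna().nunique() <= 1:
            warnings.warn(f"trait {trait!r} is constant; excluded")
            continue
        for module in eigengenes.columns:
            ev = eigengenes[module]
            mask = tv.notna() & ev.notna()
            r, p = stats.pearsonr(ev[mask], tv[mask])
            rows.append({"module": module, "trait": trait,
                         "r": float(r), "p_value": float(p),
                         "n": int(mask.sum())})
    return pd.DataFrame(rows)


def subgroup_clustering(matrix: ExpressionMatrix, k: int,
                        ) -> SubgroupAssignment:
    """Cluster participants on correlation distance between signatures.

    Profiles are per-probe centered across participants before the
    Pearson correlation, then average-linkage clustering on 1 - r is cut
    into k groups.  Subgroup indices (1..k) are assigned by first
    appearance in sample order, so the numbering is deterministic.
    """
    if k < 1 or k > matrix.n_samples:
        raise ValidationError(
            f"k={k} out of range for {matrix.n_samples} participants")
    if k == 1:
        return SubgroupAssignment({s: 1 for s in matrix.sample_ids}, 1)
    x = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    cor = np.corrcoef(x.T)
    d = np.clip(1.0 - cor, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    flat = fcluster(link, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = {}
    for sid, c in zip(matrix.sample_ids, flat):
        if int(c) not in remap:
            remap[int(c)] = len(remap) + 1
        labels[sid] = remap[int(c)]
    return SubgroupAssignment(labels, k=k, linkage=link)


def subgroup_clinical_comparison(subgroups: SubgroupAssignment,
                                 endpoints: list[EndpointRecord],
                                 samples: SampleTable,
                                 ) -> dict[str, pd.DataFrame]:
    """Subgroup means plus pairwise t-tests and an age KS comparison.

    Means per arm x subgroup for each metric (percent change per visit,
    decline slope, age, baseline AUC); two-tailed unpaired t tests
    between subgroups within arm and between arms within subgroup;
    two-sample Kolmogorov-Smirnov test of age distributions between
    subgroup pairs.  Subgroups of size < 2 appear descriptively only.
    """
    by_participant = {r.participant_id: r for r in samples.records
                      if r.timepoint_months == 0.0}
    group_of: dict[str, int] = {}
    for sid, g in subgroups.labels.items():
        rec = samples.by_sample().get(sid)
        pid = rec.participant_id if rec is not None else sid
        group_of[pid] = g

    metrics: dict[str, dict[tuple[str, int], list[float]]] = {}

    def add(metric: str, arm: str, g: int, value: float) -> None:
        if np.isfinite(value):
            metrics.setdefault(metric, {}).setdefault((arm, g), []).append(value)

    for e in endpoints:
        g = group_of.get(e.participant_id)
        if g is None:
            continue
        for t, v in e.pct_change_by_visit.items():
            if t > 0:
                add(f"pct_change_{t:g}m", e.arm, g, v)
        add("decline_slope", e.arm, g, e.decline_slope)
        add("baseline_auc", e.arm, g, e.baseline_auc)
        meta = by_participant.get(e.participant_id)
        if meta is not None:
            add("age_years", e.arm, g, meta.age_years)

    mean_rows = []
    for metric, cells in sorted(metrics.items()):
        for (arm, g), vals in sorted(cells.items()):
            mean_rows.append({"metric": metric, "arm": arm, "subgroup": g,
                              "n": len(vals), "mean": float(np.mean(vals)),
                              "sd": float(np.std(vals, ddof=1))
                              if len(vals) > 1 else float("nan")})

    test_rows = []
    for metric, cells in sorted(metrics.items()):
        keys = sorted(k for k, v in cells.items() if len(v) >= 2)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                same_arm = ka[0] == kb[0]
                same_group = ka[1] == kb[1]
                if not (same_arm or same_group):
                    continue
                t, p = stats.ttest_ind(cells[ka], cells[kb], equal_var=False)
                test_rows.append({
                    "metric": metric, "arm_a": ka[0], "subgroup_a": ka[1],
                    "arm_b": kb[0], "subgroup_b": kb[1],
                    "t": float(t), "p_value": float(p)})

    ks_rows = []
    ages = metrics.get("age_years", {})
    age_keys = sorted(k for k, v in ages.items() if len(v) >= 2)
    for i, ka in enumerate(age_keys):
        for kb in age_keys[i + 1:]:
            ks, p = stats.ks_2samp(ages[ka], ages[kb])
            ks_rows.append({
                "arm_a": ka[0], "subgroup_a": ka[1],
                "arm_b": kb[0], "subgroup_b": kb[1],
                "ks_statistic": float(ks), "p_value": float(p)})

    return {"means": pd.DataFrame(mean_rows),
            "t_tests": pd.DataFrame(test_rows),
            "ks_age": pd.DataFrame(ks_rows)}
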