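"""Synthetic cohorts with planted statistical structure.

Two generators emulate the study designs the analysis pipeline consumes:

``generate_cross_sectional``
    Four cohorts (recent-onset type 1 diabetes ROT1D n=47, low-HLA-risk
    siblings LRS n=42, high-HLA-risk siblings HRS n=30, unrelated healthy
    controls uHC n=44) with opposed gene programs: inflammatory signal
    probes elevated in ROT1D and LRS, regulatory signal probes elevated
    in HRS and uHC, everything else exchangeable noise.  Per-probe
    baseline means include a low-intensity tail so the intensity filter
    has something to remove.

``generate_trial``
    A 2:1 treated:placebo trial (54 treated, 20 placebo) with

    * a latent inflammatory index per participant, drawn around
      subgroup-specific means (four planted subgroups), expressed in the
      baseline signature as +index/2 on inflammatory probes and
      -index/2 on regulatory probes, so the composite index is an
      identifiable planted quantity;
    * three planted co-expression module blocks driven by latent factors
      with subgroup-patterned means, coupled to baseline C-peptide AUC,
      the rate of C-peptide decline, and the index itself;
    * placebo percent-change outcomes at 3/6/12/18/24 months whose
      conditional mean is ``placebo_coupling_slope * index + intercept``
      (treated outcomes decoupled from the index, with a small
      subgroup-specific benefit, largest in the high-inflammation
      subgroups);
    * remission durations from a Weibull accelerated-failure-time model
      with log-scale linear in the index, administratively censored at
      the 24 month visit; the IDAA1c series crosses its threshold at a
      fraction of the C-peptide remission time, so IDAA1c-based
      durations systematically underestimate C-peptide-based ones;
    * a planted subset of treated "responders" whose outcomes are
      displaced upward, relative to the placebo reference lines, by a
      configurable number of residual standard deviations.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .io_data_model import (
    ClinicalCourse,
    ExpressionMatrix,
    GeneSetPartition,
    SampleRecord,
    SampleTable,
    ValidationError,
)

# Subgroup geometry.  Index means rise from the regulatory-biased
# subgroups (1, 2) to the inflammatory-biased ones (3, 4).  Each
# subgroup's module-factor center vector sums to zero across the three
# modules: participant-level correlation distance removes the mean over
# probes, so only the zero-sum part of a pattern is visible to the
# subgroup clustering.  Factor 2's pattern across subgroups is
# proportional to the (centered) index pattern, making module 2 the
# index-linked module; the remaining contrast separates the other pairs.
SUBGROUP_INDEX_MEANS = (-0.30, 0.00, 0.50, 0.90)
_M_CENTERED = tuple(m - sum(SUBGROUP_INDEX_MEANS) / 4 for m in SUBGROUP_INDEX_MEANS)
_C2 = tuple(3.6 * m for m in _M_CENTERED)
_D = (1.36, -3.27, 3.27, -1.36)   # 5 * unit vector orthogonal to 1 and _C2
FACTOR_CENTERS = (
    tuple((-c + d) / 2 for c, d in zip(_C2, _D)),  # z1
    _C2,                                           # z2: index-aligned
    tuple((-c - d) / 2 for c, d in zip(_C2, _D)),  # z3
)
FACTOR_WITHIN_SD = 0.5
INDEX_WITHIN_SD = 0.25

# Clinical model constants (percent scale, months).
PCT_DECLINE_PER_MONTH = -2.2       # shared relative decline trend, %/month
PCT_PARTICIPANT_SD = 0.25          # participant-level outcome shift, %
PCT_VISIT_SD = 0.35                # per-visit outcome noise, %
BASELINE_AUC_MEDIAN = 0.45         # nmol/l
AUC_LOG_COUPLING = {"z1": 0.20, "z3": -0.20, "logT": 0.22, "noise": 0.06}


@dataclass
class SimulationConfig:
    """Planted-structure parameters; defaults mirror the study conditions."""

    n_probes: int = 5000
    n_signal_inflammatory: int = 100
    n_signal_regulatory: int = 250
    cohort_sizes: dict[str, int] = field(default_factory=lambda: {
        "ROT1D": 47, "LRS": 42, "HRS": 30, "uHC": 44})
    trial_n_treated: int = 54
    trial_n_placebo: int = 20
    effect_size_log2: float = 0.6
    noise_sd_log2: float = 0.5
    placebo_coupling_slope: float = -0.85   # % change per index unit
    weibull_shape: float = 1.5
    weibull_log_scale_coef: float = -0.8    # per index unit
    n_subgroups: int = 4
    seed: int = 0
    # Generator constants beyond the named study conditions.
    n_module_probes: int = 80               # probes per planted module block
    module_loading: float = 0.7             # expression shift per factor unit
    low_intensity_fraction: float = 0.15    # probes in the dim tail
    weibull_log_scale0: float = math.log(20.0)   # months, at index 0
    treated_log_scale_bonus: float = 0.25   # remission extension, treated arm
    idaa1c_duration_factor: float = 0.6     # IDAA1c crossing vs C-peptide time
    subgroup_benefit_pct: tuple[float, ...] = (0.0, 0.1, 0.3, 0.25)
    responder_fraction: float = 0.15
    responder_sd_displacement: float = 3.0  # timepoint displacement, in SD
    responder_slope_boost_pct_per_month: float = 3.0
    visit_months: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 18.0, 24.0)

    def __post_init__(self) -> None:
        n_signal = self.n_signal_inflammatory + self.n_signal_regulatory
        if n_signal >= self.n_probes:
            raise ValidationError("signal probe counts must be < n_probes")
        if self.noise_sd_log2 <= 0:
            raise ValidationError("noise_sd_log2 must be > 0")
        for name in ("n_probes", "trial_n_treated", "trial_n_placebo"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if any(v <= 0 for v in self.cohort_sizes.values()):
            raise ValidationError("cohort sizes must be positive")
        if self.effect_size_log2 < 0:
            raise ValidationError("effect_size_log2 must be >= 0")


@dataclass
class Truth:
    """Planted parameters carried alongside a synthetic study."""

    inflammatory_probes: list[str]
    regulatory_probes: list[str]
    module_probes: dict[str, list[str]] = field(default_factory=dict)
    subgroup: dict[str, int] = field(default_factory=dict)
    index: dict[str, float] = field(default_factory=dict)
    factors: dict[str, tuple[float, ...]] = field(default_factory=dict)
    coupling_slope: float = 0.0
    remission_months: dict[str, float] = field(default_factory=dict)
    remission_censored: dict[str, bool] = field(default_factory=dict)
    responders: set[str] = field(default_factory=set)
    baseline_auc: dict[str, float] = field(default_factory=dict)

    def partition(self) -> GeneSetPartition:
        return GeneSetPartition(set(self.inflammatory_probes),
                                set(self.regulatory_probes))


@dataclass
class SyntheticStudy:
    matrix: ExpressionMatrix | None
    samples: SampleTable
    clinical: list[ClinicalCourse]
    truth: Truth


def _probe_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"P{i:0{width}d}" for i in range(n)]


def _baseline_probe_means(rng: np.random.Generator, config: SimulationConfig,
                          n_signal_and_modules: int) -> np.ndarray:
    """Per-probe baseline log2 means with a low-intensity tail.

    Signal and module probes are kept bright so the planted structure
    survives the intensity filter; a fraction of the remaining probes
    sits in a dim tail (max log2 below the 4 RFU floor).
    """
    n = config.n_probes
    mu = rng.uniform(4.2, 11.0, size=n)
    mu[:n_signal_and_modules] = rng.uniform(6.0, 10.0,
                                            size=n_signal_and_modules)
    n_free = n - n_signal_and_modules
    n_dim = int(round(config.low_intensity_fraction * n_free))
    if n_dim > 0:
        dim_rows = n_signal_and_modules + rng.choice(n_free, size=n_dim,
                                                     replace=False)
        mu[dim_rows] = rng.uniform(1.0, 2.2, size=n_dim)
    return mu


# ---------------------------------------------------------------------------
# Cross-sectional cohorts
# ---------------------------------------------------------------------------

_COHORT_AGE = {"ROT1D": (10.0, 2.9), "LRS": (8.4, 2.0),
               "HRS": (8.6, 1.9), "uHC": (15.0, 4.1)}

# Graded program strength: the inflammatory program is strongest in the
# diabetic cohort and weaker in low-HLA-risk siblings; the regulatory
# program is strongest in high-HLA-risk siblings and weaker in controls.
# The grading makes the cohort mean-index ordering
# ROT1D > LRS > uHC > HRS an identifiable planted feature.
_INFLAMMATORY_WEIGHT = {"ROT1D": 1.0, "LRS": 0.8}
_REGULATORY_WEIGHT = {"HRS": 1.0, "uHC": 0.8}


def generate_cross_sectional(config: SimulationConfig) -> SyntheticStudy:
    """Four cohorts with opposed inflammatory / regulatory programs."""
    rng = np.random.default_rng(config.seed)
    probes = _probe_ids(config.n_probes)
    ni, nr = config.n_signal_inflammatory, config.n_signal_regulatory
    infl = probes[:ni]
    reg = probes[ni:ni + nr]

    cohorts, sample_ids, ages = [], [], []
    for cohort in ("ROT1D", "LRS", "HRS", "uHC"):
        size = config.cohort_sizes.get(cohort, 0)
        mean_age, sd_age = _COHORT_AGE[cohort]
        for k in range(size):
            sample_ids.append(f"{cohort}_{k:03d}")
            cohorts.append(cohort)
            ages.append(max(1.0, rng.normal(mean_age, sd_age)))

    mu = _baseline_probe_means(rng, config, ni + nr)
    values = mu[:, None] + rng.normal(
        0.0, config.noise_sd_log2, size=(config.n_probes, len(sample_ids)))
    infl_weight = np.array([_INFLAMMATORY_WEIGHT.get(c, 0.0) for c in cohorts])
    reg_weight = np.array([_REGULATORY_WEIGHT.get(c, 0.0) for c in cohorts])
    values[:ni, :] += config.effect_size_log2 * infl_weight[None, :]
    values[ni:ni + nr, :] += config.effect_size_log2 * reg_weight[None, :]

    matrix = ExpressionMatrix(probes, sample_ids, values)
    samples = SampleTable([
        SampleRecord(sample_id=s, participant_id=s, cohort=c,
                     arm="none", timepoint_months=0.0, age_years=a)
        for s, c, a in zip(sample_ids, cohorts, ages)])
    truth = Truth(inflammatory_probes=list(infl), regulatory_probes=list(reg))
    return SyntheticStudy(matrix=matrix, samples=samples, clinical=[],
                          truth=truth)


# ---------------------------------------------------------------------------
# Two-arm longitudinal trial
# ---------------------------------------------------------------------------

def generate_trial(config: SimulationConfig,
                   with_expression: bool = True) -> SyntheticStudy:
    """2:1 treated:placebo trial with planted index, subgroups and outcomes."""
    rng = np.random.default_rng(config.seed)
    n_total = config.trial_n_treated + config.trial_n_placebo
    pids = [f"T{k:03d}" for k in range(n_total)]
    arms = (["treated"] * config.trial_n_treated
            + ["placebo"] * config.trial_n_placebo)
    order = rng.permutation(n_total)
    pids = [pids[i] for i in order]  # decouple id order from arm order
    pids.sort()
    # (ids are relabelled after shuffling so arm is not encoded in order)
    arm_of = dict(zip(pids, [arms[i] for i in order]))

    k_sub = config.n_subgroups
    subgroup = {p: int(rng.integers(0, k_sub)) for p in pids}
    index = {p: SUBGROUP_INDEX_MEANS[subgroup[p] % 4]
             + rng.normal(0.0, INDEX_WITHIN_SD) for p in pids}
    factors = {}
    for p in pids:
        g = subgroup[p] % 4
        factors[p] = tuple(FACTOR_CENTERS[k][g]
                           + rng.normal(0.0, FACTOR_WITHIN_SD)
                           for k in range(3))

    # Remission times: Weibull AFT, log-scale linear in the index.
    remission, censored = {}, {}
    horizon = max(config.visit_months)
    for p in pids:
        log_scale = (config.weibull_log_scale0
                     + config.weibull_log_scale_coef * index[p])
        if arm_of[p] == "treated":
            log_scale += config.treated_log_scale_bonus
        t_event = math.exp(log_scale) * rng.weibull(config.weibull_shape)
        remission[p] = float(min(t_event, horizon))
        censored[p] = bool(t_event > horizon)

    # Responders: a random subset of the treated arm, displaced upward
    # relative to the placebo reference lines.
    treated_ids = [p for p in pids if arm_of[p] == "treated"]
    n_resp = int(round(config.responder_fraction * len(treated_ids)))
    responders = (set(map(str, rng.choice(treated_ids, size=n_resp,
                                          replace=False)))
                  if n_resp else set())

    # Standardisation constants for the latent factors (population scale).
    f_sd = [math.sqrt(float(np.mean(np.square(FACTOR_CENTERS[k])))
                      + FACTOR_WITHIN_SD ** 2) for k in range(3)]

    clinical = []
    baseline_auc = {}
    visits = list(config.visit_months)
    sd_tp = math.sqrt(PCT_PARTICIPANT_SD ** 2 + PCT_VISIT_SD ** 2)
    for p in pids:
        z1c = factors[p][0] / f_sd[0]
        z3c = factors[p][2] / f_sd[2]
        log_t = math.log(max(remission[p], 1e-6))
        log_t_c = (log_t - config.weibull_log_scale0) / 0.9
        auc0 = BASELINE_AUC_MEDIAN * math.exp(
            AUC_LOG_COUPLING["z1"] * z1c + AUC_LOG_COUPLING["z3"] * z3c
            + AUC_LOG_COUPLING["logT"] * log_t_c
            + AUC_LOG_COUPLING["noise"] * rng.normal())
        baseline_auc[p] = auc0
        u = rng.normal(0.0, PCT_PARTICIPANT_SD)
        g = subgroup[p] % 4
        auc_series, hba1c_series, dose_series = [], [], []
        t_idaa = (config.idaa1c_duration_factor * remission[p]
                  * math.exp(rng.normal(0.0, 0.2)))
        for t in visits:
            if t == 0.0:
                auc_series.append(auc0)
            else:
                pct = (PCT_DECLINE_PER_MONTH * t + u
                       + rng.normal(0.0, PCT_VISIT_SD))
                if arm_of[p] == "placebo":
                    pct += config.placebo_coupling_slope * index[p]
                else:
                    pct += config.subgroup_benefit_pct[g]
                if p in responders:
                    pct += (config.responder_sd_displacement * sd_tp
                            + config.responder_slope_boost_pct_per_month * t)
                auc_series.append(max(0.0, auc0 * (1.0 + pct / 100.0)))
            # IDAA1c crosses 9 at t_idaa; insulin dose rises slowly.
            dose = 0.40 + 0.015 * t
            idaa = 8.2 + 1.6 * (t - t_idaa) / 12.0
            idaa = min(max(idaa, 6.5), 13.0) + rng.normal(0.0, 0.03)
            hba1c_series.append(idaa - 4.0 * dose)
            dose_series.append(dose)
        clinical.append(ClinicalCourse(
            participant_id=p, visit_times_months=visits,
            cpeptide_auc_nmol_l=auc_series, hba1c_percent=hba1c_series,
            insulin_u_per_kg_day=dose_series, arm=arm_of[p]))

    # Baseline expression: index on the signature probes, factors on the
    # module blocks, noise elsewhere.
    probes = _probe_ids(config.n_probes)
    ni, nr = config.n_signal_inflammatory, config.n_signal_regulatory
    nm = config.n_module_probes
    infl = probes[:ni]
    reg = probes[ni:ni + nr]
    module_probes = {f"M{k + 1}": probes[ni + nr + k * nm:ni + nr + (k + 1) * nm]
                     for k in range(3)}
    matrix = None
    sample_records = []
    if with_expression:
        mu = _baseline_probe_means(rng, config, ni + nr + 3 * nm)
        values = mu[:, None] + rng.normal(
            0.0, config.noise_sd_log2, size=(config.n_probes, n_total))
        x = np.array([index[p] for p in pids])
        values[:ni, :] += x[None, :] / 2.0
        values[ni:ni + nr, :] -= x[None, :] / 2.0
        for k in range(3):
            zk = np.array([factors[p][k] for p in pids])
            rows = slice(ni + nr + k * nm, ni + nr + (k + 1) * nm)
            values[rows, :] += config.module_loading * zk[None, :]
        matrix = ExpressionMatrix(probes, [f"{p}_m0" for p in pids], values)
    for p in pids:
        sample_records.append(SampleRecord(
            sample_id=f"{p}_m0", participant_id=p, cohort="TRIAL",
            arm=arm_of[p], timepoint_months=0.0,
            age_years=max(4.0, rng.normal(14.7, 6.8))))
    samples = SampleTable(sample_records)

    truth = Truth(
        inflammatory_probes=list(infl), regulatory_probes=list(reg),
        module_probes=module_probes,
        subgroup={p: subgroup[p] + 1 for p in pids},
        index=index, factors=factors,
        coupling_slope=config.placebo_coupling_slope,
        remission_months=remission, remission_censored=censored,
        responders=responders, baseline_auc=baseline_auc)
    return SyntheticStudy(matrix=matrix, samples=samples, clinical=clinical,
                          truth=truth)


# ---------------------------------------------------------------------------
# Paired signed signatures (spike-in emulation)
# ---------------------------------------------------------------------------

def generate_paired_signatures(n_probes: int, concordant_fraction: float,
                               seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two signed log2-ratio vectors with an exact concordant count.

    Exactly ``round(concordant_fraction * n_probes)`` positions carry
    matching signs between the two vectors; magnitudes are random.
    """
    if n_probes < 1:
        raise ValidationError("n_probes must be >= 1")
    if not 0.0 <= concordant_fraction <= 1.0:
        raise ValidationError("concordant_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sign_a = rng.choice([-1.0, 1.0], size=n_probes)
    a = sign_a * (0.263 + rng.exponential(0.4, size=n_probes))
    n_conc = int(round(concordant_fraction * n_probes))
    agree = np.zeros(n_probes, dtype=bool)
    agree[rng.choice(n_probes, size=n_conc, replace=False)] = True
    sign_b = np.where(agree, sign_a, -sign_a)
    b = sign_b * (0.05 + rng.exponential(0.4, size=n_probes))
    return a, b
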