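"""Core domain types, tab-separated readers/writers and validation.

Everything downstream operates on three tables: a probe-by-sample log2
expression matrix, a sample metadata table (cohort, arm, timepoint, age)
and a long-format clinical table carrying per-visit stimulated C-peptide
AUC, HbA1c and weight-normalised insulin dose.  All files are UTF-8,
tab-separated, header row, identifiers in the first column.  Missing
clinical values are empty cells, never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COHORTS = ("ROT1D", "LRS", "HRS", "uHC", "TRIAL")
CROSS_SECTIONAL_COHORTS = ("ROT1D", "LRS", "HRS", "uHC")
ARMS = ("placebo", "treated", "none")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 intensities (RFU, log2 scale)."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at probe "
                f"{self.probe_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.probe_index()
        rows = [idx[p] for p in probes]
        return ExpressionMatrix(list(probes), list(self.sample_ids),
                                self.values[rows, :])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index()
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.probe_ids), list(samples),
                                self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=self.sample_ids)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    sample_id: str
    participant_id: str
    cohort: str
    arm: str = "none"
    timepoint_months: float = 0.0
    age_years: float = float("nan")

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}")
        if (self.arm == "none") != (self.cohort != "TRIAL"):
            raise ValidationError(
                f"sample {self.sample_id!r}: arm must be 'none' iff cohort is "
                f"not TRIAL (got cohort={self.cohort!r}, arm={self.arm!r})"
            )
        if self.timepoint_months < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative timepoint")


@dataclass
class SampleTable:
    """Per-sample metadata; one row per sample_id."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        _check_unique([r.sample_id for r in self.records], "sample")

    def __len__(self) -> int:
        return len(self.records)

    def by_sample(self) -> dict[str, SampleRecord]:
        return {r.sample_id: r for r in self.records}

    def cohort_of(self) -> dict[str, str]:
        return {r.sample_id: r.cohort for r in self.records}

    def samples_in_cohort(self, cohort: str) -> list[str]:
        return [r.sample_id for r in self.records if r.cohort == cohort]

    def samples_in_arm(self, arm: str) -> list[str]:
        return [r.sample_id for r in self.records if r.arm == arm]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


# ---------------------------------------------------------------------------
# Clinical course
# ---------------------------------------------------------------------------

@dataclass
class ClinicalCourse:
    """Per-participant visit series.

    ``cpeptide_auc_nmol_l`` is the 2 h stimulated C-peptide AUC (nmol/l).
    Optional series (HbA1c %, insulin U kg-1 day-1) are ``None`` when the
    cohort lacks the measurement; when present they align with
    ``visit_times_months``.  A baseline visit (month 0) is mandatory.
    """

    participant_id: str
    visit_times_months: list[float]
    cpeptide_auc_nmol_l: list[float] | None = None
    hba1c_percent: list[float] | None = None
    insulin_u_per_kg_day: list[float] | None = None
    arm: str = "placebo"

    def __post_init__(self) -> None:
        t = list(map(float, self.visit_times_months))
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError(
                f"participant {self.participant_id!r}: visit times must be "
                f"strictly increasing, got {t}")
        if not t or t[0] != 0.0:
            raise ValidationError(
                f"participant {self.participant_id!r}: baseline visit missing")
        self.visit_times_months = t
        for name in ("cpeptide_auc_nmol_l", "hba1c_percent",
                     "insulin_u_per_kg_day"):
            series = getattr(self, name)
            if series is not None:
                series = [None if v is None or (isinstance(v, float) and math.isnan(v))
                          else float(v) for v in series]
                if len(series) != len(t):
                    raise ValidationError(
                        f"participant {self.participant_id!r}: {name} length "
                        f"{len(series)} != {len(t)} visits")
                setattr(self, name, series)
        if self.arm not in ("placebo", "treated"):
            raise ValidationError(f"unknown arm {self.arm!r}")

    def baseline_auc(self) -> float:
        if self.cpeptide_auc_nmol_l is None or self.cpeptide_auc_nmol_l[0] is None:
            raise ValidationError(
                f"participant {self.participant_id!r}: no baseline C-peptide AUC")
        return float(self.cpeptide_auc_nmol_l[0])


# ---------------------------------------------------------------------------
# Gene-set partition and thresholds
# ---------------------------------------------------------------------------

@dataclass
class GeneSetPartition:
    """Disjoint inflammatory and regulatory probe sets (the index definition)."""

    inflammatory_probes: set[str]
    regulatory_probes: set[str]

    def __post_init__(self) -> None:
        self.inflammatory_probes = set(map(str, self.inflammatory_probes))
        self.regulatory_probes = set(map(str, self.regulatory_probes))
        if not self.inflammatory_probes or not self.regulatory_probes:
            raise ValidationError("both partition sets must be non-empty")
        overlap = self.inflammatory_probes & self.regulatory_probes
        if overlap:
            raise ValidationError(
                f"partition sets overlap: {sorted(overlap)[:5]} ...")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.probe_ids)
        missing = (self.inflammatory_probes | self.regulatory_probes) - known
        if missing:
            raise ValidationError(
                f"partition probes absent from matrix: {sorted(missing)[:5]} ...")


@dataclass
class Thresholds:
    """Tunable analysis thresholds.

    Defaults follow the study's reported cut-offs: 1.2-fold regulation
    (|log2 ratio| > 0.263) at FDR < 20 %, random-forest Gini > 3.49,
    remission floors (C-peptide 0.2 nmol/l, IDAA1c 9), responder rules
    (> 1.5 SD at >= 3 timepoints, > 1 SD on the slope line), network
    soft power 12 with scale-free fit R^2 > 0.8, top-7000 MAD retention
    and the low-intensity floor (max log2 < 4 RFU).
    """

    log2_fc: float = 0.263
    diff_fdr: float = 0.20
    diff_alpha: float = 0.05
    response_alpha: float = 0.02
    response_fdr: float = 0.30
    gini_min: float = 3.49
    cpeptide_floor_nmol_l: float = 0.2
    idaa1c_max: float = 9.0
    responder_sd_timepoint: float = 1.5
    responder_min_timepoints: int = 3
    responder_sd_slope: float = 1.0
    soft_power: int = 12
    scale_free_r2_min: float = 0.8
    mad_keep: int = 7000
    low_intensity_log2_max: float = 4.0
    n_subgroups: int = 4

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValidationError(f"threshold {f.name} must be positive, got {v}")
        if not 0 < self.diff_fdr < 1:
            raise ValidationError("diff_fdr must lie in (0, 1)")

    @classmethod
    def from_config(cls, config: Mapping[str, object] | None = None,
                    **overrides: object) -> "Thresholds":
        """Build thresholds from a config mapping, then keyword overrides."""
        merged: dict[str, object] = {}
        names = {f.name for f in dataclasses.fields(cls)}
        for source in (config or {}), overrides:
            for k, v in source.items():
                if v is None:
                    continue
                if k not in names:
                    raise ValidationError(f"unknown threshold {k!r}")
                merged[k] = v
        return cls(**merged)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated probe-by-sample matrix (probe IDs in column 1)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(probe_ids, "probe")
    _check_unique(sample_ids, "sample")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric value {raw!r} at probe "
                    f"{probe_ids[i]!r} (row {i + 2}), sample {sample_ids[j]!r} "
                    f"(column {j + 2})") from None
    return ExpressionMatrix(probe_ids, sample_ids, values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                            "participant_id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(SampleRecord(
            sample_id=str(row.sample_id),
            participant_id=str(row.participant_id),
            cohort=str(row.cohort),
            arm=str(getattr(row, "arm", "none")),
            timepoint_months=float(getattr(row, "timepoint_months", 0.0)),
            age_years=float(getattr(row, "age_years", float("nan"))),
        ))
    return SampleTable(records)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


_CLINICAL_SERIES = ("cpeptide_auc_nmol_l", "hba1c_percent", "insulin_u_per_kg_day")


def read_clinical_table(path: str | Path) -> list[ClinicalCourse]:
    """Read a long-format clinical table into per-participant courses.

    Expected columns: participant_id, visit_months, arm, then any of
    cpeptide_auc_nmol_l / hba1c_percent / insulin_u_per_kg_day.  Visits
    may arrive in any order; they are sorted ascending.  A series absent
    for every visit of a participant is flagged absent (None), not zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    courses = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("visit_months")
        times = [float(t) for t in grp["visit_months"]]
        if times and times[0] != 0.0:
            raise ValidationError(
                f"participant {pid!r}: baseline visit missing")
        kwargs: dict[str, object] = {}
        for name in _CLINICAL_SERIES:
            if name in grp.columns and grp[name].notna().any():
                kwargs[name] = [None if pd.isna(v) else float(v)
                                for v in grp[name]]
        arm = str(grp["arm"].iloc[0]) if "arm" in grp.columns else "placebo"
        courses.append(ClinicalCourse(
            participant_id=str(pid), visit_times_months=times,
            arm=arm, **kwargs))  # type: ignore[arg-type]
    return courses


def write_clinical_table(courses: Iterable[ClinicalCourse],
                         path: str | Path) -> None:
    rows = []
    for c in courses:
        for i, t in enumerate(c.visit_times_months):
            row: dict[str, object] = {
                "participant_id": c.participant_id,
                "visit_months": t,
                "arm": c.arm,
            }
            for name in _CLINICAL_SERIES:
                series = getattr(c, name)
                row[name] = "" if series is None or series[i] is None else series[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_partition(path: str | Path) -> GeneSetPartition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    infl = set(df.loc[df["set"] == "inflammatory", "probe_id"])
    reg = set(df.loc[df["set"] == "regulatory", "probe_id"])
    return GeneSetPartition(infl, reg)


def write_partition(partition: GeneSetPartition, path: str | Path) -> None:
    rows = [{"probe_id": p, "set": "inflammatory"}
            for p in sorted(partition.inflammatory_probes)]
    rows += [{"probe_id": p, "set": "regulatory"}
             for p in sorted(partition.regulatory_probes)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
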