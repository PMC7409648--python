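"""Cohort data model: patient records, the platelet-recovery marker, and
dichotomization.

The marker of interest is the platelet recovery degree

    ``dplt = plt_peak - plt_pre``

where ``plt_pre`` is the peripheral platelet count (x10^9/L) on the day
before initial induction therapy and ``plt_peak`` the peak count after
marrow recovery following the course that induced the first MRD-negative
complete remission.  Survival endpoints are progression-free survival (PFS:
time from first MRD-negative CR to relapse or death) and overall survival
(OS: time from first MRD-negative CR to death), both in months.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .survival import SurvivalSample

__all__ = [
    "PatientRecord",
    "Cohort",
    "CrAssessment",
    "compute_dplt",
    "meets_morphologic_cr",
    "dichotomize",
    "COHORT_COLUMNS",
]

SEX_LEVELS = ("male", "female")
RISK_LEVELS = ("favorable", "intermediate", "adverse")
CONSOLIDATION_LEVELS = ("AML-201", "AML-87", "HDAraC")
ENDPOINTS = ("PFS", "OS")

#: Column order of the delimited cohort format (comma separated, header row).
#: Platelet counts in x10^9/L, times in months.
COHORT_COLUMNS = [
    "patient_id",
    "plt_pre",
    "plt_peak",
    "dplt",
    "age",
    "sex",
    "risk_group",
    "courses_to_cr",
    "consolidation",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
    "wbc",
    "hemoglobin",
    "marrow_blast_pct",
]


def compute_dplt(plt_pre, plt_peak):
    """Platelet recovery degree: ``plt_peak - plt_pre``.

    Accepts scalars or arrays.  Both inputs must be finite and non-negative
    (platelet counts); the difference itself may be negative, although in
    practice recovery peaks exceed pre-treatment counts.

    Raises
    ------
    ValidationError
        Naming the offending field when an input is missing, non-finite or
        negative.
    """
    pre = np.asarray(plt_pre, dtype=float)
    peak = np.asarray(plt_peak, dtype=float)
    for name, arr in (("plt_pre", pre), ("plt_peak", peak)):
        if not np.all(np.isfinite(arr)):
            raise ValidationError("missing or non-finite platelet count", field=name)
        if np.any(arr < 0):
            raise ValidationError("platelet count must be >= 0", field=name)
    out = peak - pre
    return out.item() if out.ndim == 0 else out


@dataclass
class CrAssessment:
    """Morphological remission assessment at one time point.

    All counts x10^9/L; blast percentage of nucleated marrow cells.
    """

    marrow_blast_pct: float
    extramedullary_disease: bool
    neutrophils: float
    platelets: float

    def __post_init__(self):
        for name in ("marrow_blast_pct", "neutrophils", "platelets"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValidationError("must be a finite number >= 0", field=name)


def meets_morphologic_cr(assessment: CrAssessment) -> bool:
    """Morphological complete remission, all criteria strict:

    <5% marrow blasts, no extramedullary disease, neutrophils >1 x10^9/L and
    platelets >100 x10^9/L.
    """
    return (
        assessment.marrow_blast_pct < 5.0
        and not assessment.extramedullary_disease
        and assessment.neutrophils > 1.0
        and assessment.platelets > 100.0
    )


@dataclass
class PatientRecord:
    """One patient of the remission cohort.

    ``dplt`` is always recomputed from ``plt_pre`` and ``plt_peak``; survival
    fields are required, baseline covariates may be ``None`` (tolerated for
    Kaplan-Meier / log-rank, dropped listwise by regression and baseline
    comparisons).
    """

    patient_id: str
    plt_pre: float
    plt_peak: float
    pfs_time: float
    pfs_event: int
    os_time: float
    os_event: int
    age: float | None = None
    sex: str | None = None
    risk_group: str | None = None
    courses_to_cr: int | None = None
    consolidation: str | None = None
    wbc: float | None = None
    hemoglobin: float | None = None
    marrow_blast_pct: float | None = None
    dplt: float = field(init=False)

    def __post_init__(self):
        self.dplt = compute_dplt(self.plt_pre, self.plt_peak)
        for name in ("pfs_time", "pfs_event", "os_time", "os_event"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                raise ValidationError("survival field is required", field=name)
        for name in ("pfs_time", "os_time"):
            if getattr(self, name) < 0:
                raise ValidationError("time must be >= 0", field=name)
        for name in ("pfs_event", "os_event"):
            if getattr(self, name) not in (0, 1):
                raise ValidationError("event indicator must be 0 or 1", field=name)
        if self.sex is not None and self.sex not in SEX_LEVELS:
            raise ValidationError(f"unknown level {self.sex!r}", field="sex")
        if self.risk_group is not None and self.risk_group not in RISK_LEVELS:
            raise ValidationError(f"unknown level {self.risk_group!r}", field="risk_group")
        if self.consolidation is not None and self.consolidation not in CONSOLIDATION_LEVELS:
            raise ValidationError(
                f"unknown level {self.consolidation!r}", field="consolidation"
            )
        if self.courses_to_cr is not None and self.courses_to_cr < 1:
            raise ValidationError("must be >= 1", field="courses_to_cr")
        # OS >= PFS is expected clinically but not enforced: warn only.
        if self.os_time < self.pfs_time:
            warnings.warn(
                f"patient {self.patient_id}: os_time < pfs_time "
                f"({self.os_time} < {self.pfs_time})",
                stacklevel=2,
            )


class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique ids.

    The ordering is stable and significant: random splits and seeded
    simulations are reproducible only relative to it.
    """

    def __init__(
        self,
        records: Iterable[PatientRecord],
        provenance: str = "",
        metadata: dict | None = None,
    ):
        self.records: list[PatientRecord] = list(records)
        self.provenance = provenance
        self.metadata = dict(metadata or {})
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate ids: {dupes}", field="patient_id")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def marker(self, name: str = "dplt") -> np.ndarray:
        """Marker values in cohort order as a float array."""
        try:
            return np.array([getattr(r, name) for r in self.records], dtype=float)
        except AttributeError:
            raise ValidationError(f"unknown marker field {name!r}", field=name)

    def survival_sample(
        self,
        endpoint: str = "PFS",
        group: Sequence | None = None,
        stratum: Sequence | None = None,
    ) -> SurvivalSample:
        """Extract one endpoint as a :class:`SurvivalSample`."""
        if endpoint not in ENDPOINTS:
            raise ValidationError(f"endpoint must be one of {ENDPOINTS}", field="endpoint")
        pre = endpoint.lower()
        time = np.array([getattr(r, f"{pre}_time") for r in self.records], dtype=float)
        event = np.array([getattr(r, f"{pre}_event") for r in self.records], dtype=int)
        return SurvivalSample(time=time, event=event, group=group, stratum=stratum)

    def subset(self, patient_ids: Iterable[str], provenance: str | None = None) -> "Cohort":
        wanted = set(patient_ids)
        recs = [r for r in self.records if r.patient_id in wanted]
        missing = wanted - {r.patient_id for r in recs}
        if missing:
            raise ValidationError(f"unknown ids: {sorted(missing)}", field="patient_id")
        return Cohort(recs, provenance=provenance or self.provenance)

    # -- delimited text interface -------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{c: getattr(r, c) for c in COHORT_COLUMNS} for r in self.records]
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        required = [
            c for c in COHORT_COLUMNS if c not in ("dplt", "wbc", "hemoglobin", "marrow_blast_pct")
        ]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}", field=missing[0])
        records = []
        for _, row in df.iterrows():
            kwargs = {}
            for f in fields(PatientRecord):
                if not f.init or f.name not in df.columns:
                    continue
                v = row[f.name]
                if pd.isna(v):
                    v = None
                kwargs[f.name] = v
            kwargs["patient_id"] = str(kwargs["patient_id"])
            for intfield in ("pfs_event", "os_event"):
                kwargs[intfield] = int(kwargs[intfield])
            if kwargs.get("courses_to_cr") is not None:
                kwargs["courses_to_cr"] = int(kwargs["courses_to_cr"])
            records.append(PatientRecord(**kwargs))
        return cls(records, provenance=provenance)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Cohort":
        return cls.from_dataframe(pd.read_csv(path), provenance=str(path))


def dichotomize(values, cutoff, labels: tuple[str, str] = ("high", "low"), strict: bool = True):
    """Split marker values into two groups at ``cutoff``.

    By default (``strict=True``) "high" means strictly greater than the
    cutoff, so a cutoff chosen from the observed values leaves its defining
    patient in the low group — the convention of the maximally-selected-
    statistic literature.  ``strict=False`` uses >= instead.

    Returns an object array of ``labels[0]`` (high) / ``labels[1]`` (low).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot dichotomize an empty vector", field="values")
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite", field="cutoff")
    high = arr > cutoff if strict else arr >= cutoff
    return np.where(high, labels[0], labels[1])
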