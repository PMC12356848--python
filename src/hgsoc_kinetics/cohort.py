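"""Cohort I/O: serial lesion-volume measurements and mask-derived volumes.

The canonical on-disk form is a CSV with header
``patient_id,site,scan_day,volume_cm3`` — one measurement per row, one
row per patient x disease site x scan. In memory the cohort is a set of
:class:`LesionSeries`, each holding the time-ordered volumes of one
lesion site of one patient. Scan days are relative to an arbitrary
per-patient origin; only differences between them matter.

Lesion volumes may also be computed from 3-D binary segmentation masks
(voxel count times voxel volume), including NIfTI files when nibabel is
installed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "LesionSeries",
    "Cohort",
    "MaskSpec",
    "mask_volume",
    "nifti_mask_volume",
    "read_cohort",
    "write_cohort",
    "scan_interval_summary",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ("patient_id", "site", "scan_day", "volume_cm3")

# Accepted spellings for the two disease sites (compared lower-case,
# with spaces/hyphens collapsed to underscores).
_SITE_SYNONYMS = {
    "ovary_pelvis": "ovary_pelvis",
    "ovary": "ovary_pelvis",
    "ovaries": "ovary_pelvis",
    "pelvis": "ovary_pelvis",
    "ovaries_pelvis": "ovary_pelvis",
    "ovarian": "ovary_pelvis",
    "omentum": "omentum",
    "omental": "omentum",
}


class Site(str, enum.Enum):
    """Disease site: ovarian/pelvic primary mass or omental deposit."""

    OVARY_PELVIS = "ovary_pelvis"
    OMENTUM = "omentum"

    @classmethod
    def parse(cls, label: str) -> "Site":
        key = str(label).strip().lower().replace("/", "_").replace("-", "_").replace(" ", "_")
        try:
            return cls(_SITE_SYNONYMS[key])
        except KeyError:
            raise ValueError(
                f"unrecognised site label {label!r}; expected one of "
                f"{sorted(set(_SITE_SYNONYMS))}"
            ) from None


@dataclass(frozen=True)
class LesionSeries:
    """Ordered volume measurements of one lesion site of one patient."""

    patient_id: str
    site: Site
    scan_days: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.scan_days) != len(self.volumes):
            raise ValueError("scan_days and volumes must have equal length")
        if len(self.scan_days) == 0:
            raise ValueError("a series needs at least one measurement")
        days = np.asarray(self.scan_days, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        if not np.all(np.isfinite(days)):
            raise ValueError(f"non-finite scan_day in series {self.patient_id}/{self.site.value}")
        if not (np.all(np.isfinite(vols)) and np.all(vols >= 0)):
            raise ValueError(f"volumes must be finite and >= 0 in {self.patient_id}/{self.site.value}")
        if np.any(np.diff(days) <= 0):
            raise ValueError(
                f"scan_day must be strictly increasing in series "
                f"{self.patient_id}/{self.site.value}"
            )

    def __len__(self) -> int:
        return len(self.scan_days)


@dataclass(frozen=True)
class Cohort:
    """A collection of lesion series, unique per (patient, site)."""

    series: tuple[LesionSeries, ...]

    def __post_init__(self) -> None:
        keys = [(s.patient_id, s.site) for s in self.series]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (patient, site) series: {dupes}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def get(self, patient_id: str, site: Site | str) -> LesionSeries | None:
        site = Site.parse(site) if not isinstance(site, Site) else site
        for s in self.series:
            if s.patient_id == patient_id and s.site == site:
                return s
        return None

    def by_site(self, site: Site | str) -> list[LesionSeries]:
        site = Site.parse(site) if not isinstance(site, Site) else site
        return [s for s in self.series if s.site == site]

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.series:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.patient_id, s.site.value, d, v)
            for s in self.series
            for d, v in zip(s.scan_days, s.volumes)
        ]
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


@dataclass(frozen=True)
class MaskSpec:
    """A 3-D binary segmentation mask plus its voxel volume in cm^3."""

    mask: np.ndarray
    voxel_volume: float


def mask_volume(spec: MaskSpec) -> float:
    """Lesion volume from a binary mask: (number of lesion voxels) * dv.

    Every voxel flagged 1 contributes one voxel volume ``dv``; the total
    burden is the voxel count times ``dv``, in cm^3.
    """
    mask = np.asarray(spec.mask)
    if not np.isin(mask, (0, 1)).all():
        bad = np.unique(mask[~np.isin(mask, (0, 1))])[:5]
        raise ValueError(f"mask must contain only 0/1 values, found {bad.tolist()}")
    if not (spec.voxel_volume > 0 and np.isfinite(spec.voxel_volume)):
        raise ValueError(f"voxel_volume must be positive, got {spec.voxel_volume}")
    return float(mask.sum()) * float(spec.voxel_volume)


def nifti_mask_volume(path: str | Path) -> float:
    """Volume of a binary lesion mask stored as NIfTI (.nii / .nii.gz).

    Voxel volume is derived from the header spacing (mm^3 -> cm^3).
    Requires nibabel.
    """
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    dv_cm3 = float(np.prod(zooms)) / 1000.0
    data = np.asanyarray(img.dataobj)
    return mask_volume(MaskSpec(mask=np.rint(data).astype(np.int64), voxel_volume=dv_cm3))


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV (header ``patient_id,site,scan_day,volume_cm3``).

    Returns one :class:`LesionSeries` per (patient, site), measurements
    sorted by scan day. Duplicate (patient, site, scan_day) rows and
    unparseable numbers raise with the offending row named.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must be {COHORT_COLUMNS}")
    for col in ("scan_day", "volume_cm3"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            row = int((df.index[coerced.isna()])[0])
            raise ValueError(f"{path}: unparseable {col} value {df[col].iloc[row]!r} at data row {row + 1}")
        df[col] = coerced
    return cohort_from_frame(df, origin=str(path))


def cohort_from_frame(df: pd.DataFrame, origin: str = "<frame>") -> Cohort:
    """Build a :class:`Cohort` from a measurement table in memory."""
    df = df.copy()
    df["site"] = df["site"].map(Site.parse)
    dup = df.duplicated(subset=["patient_id", "site", "scan_day"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{origin}: duplicate measurement for patient {first['patient_id']!r}, "
            f"site {first['site'].value}, scan_day {first['scan_day']}"
        )
    series = []
    for (pid, site), grp in df.groupby(["patient_id", "site"], sort=True):
        grp = grp.sort_values("scan_day")
        series.append(
            LesionSeries(
                patient_id=str(pid),
                site=site,
                scan_days=tuple(float(d) for d in grp["scan_day"]),
                volumes=tuple(float(v) for v in grp["volume_cm3"]),
            )
        )
    return Cohort(series=tuple(series))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV in the canonical dialect (round-trips with read)."""
    cohort.to_frame().to_csv(path, index=False, float_format="%.10g")


def scan_interval_summary(cohort: Cohort) -> dict[str, float]:
    """Median and IQR (days) of per-patient first-to-second scan intervals.

    One interval per patient: the gap between that patient's first two
    scan days, pooling sites (the earliest two distinct scan days seen
    for the patient across all their series).
    """
    intervals = []
    for pid in cohort.patient_ids:
        days = sorted({d for s in cohort.series if s.patient_id == pid for d in s.scan_days})
        if len(days) >= 2:
            intervals.append(days[1] - days[0])
    if not intervals:
        raise ValueError("no patient has two or more scans")
    arr = np.asarray(intervals, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "n_patients": len(arr),
        "median_days": float(med),
        "iqr_days": (float(q1), float(q3)),
    }
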