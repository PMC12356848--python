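"""Eligibility screening and exponential doubling-time calculation.

A lesion series enters the doubling-time analysis only if it shows at
least 10% volume increase between the scans used and carries a minimum
burden of 0.05 cm^3 at the first scan — both filters guard against
segmentation artefacts dominating the growth signal.

For an eligible pair (V1, V2) measured dt months apart, the specific
growth rate under exponential growth is alpha = ln(V2/V1) / dt and the
tumour volume doubling time is TVDT = ln2 / alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort, LesionSeries, Site
from .gompertz import DAYS_PER_MONTH

__all__ = [
    "MIN_VOLUME_CM3",
    "MIN_GROWTH_FRAC",
    "GrowthRecord",
    "eligible",
    "growth_record",
    "eligible_records",
    "site_tvdt_summary",
    "compare_groups",
]

MIN_VOLUME_CM3 = 0.05
MIN_GROWTH_FRAC = 0.10


@dataclass(frozen=True)
class GrowthRecord:
    """Exponential growth summary of one eligible lesion."""

    patient_id: str
    site: Site
    v1: float  # cm^3 at first scan used
    v2: float  # cm^3 at second scan used
    dt_months: float
    alpha: float  # specific growth rate, 1/month
    tvdt_months: float


def _scan_pair(series: LesionSeries, min_volume: float, min_growth_frac: float):
    """First qualifying successive scan pair, or None.

    Most series have exactly two scans; with more, the earliest
    successive pair meeting both the burden floor and the growth
    fraction is used.
    """
    for j in range(len(series) - 1):
        v1, v2 = series.volumes[j], series.volumes[j + 1]
        if v1 >= min_volume and v1 > 0 and v2 >= (1.0 + min_growth_frac) * v1:
            return j
    return None


def eligible(
    series: LesionSeries,
    min_volume: float = MIN_VOLUME_CM3,
    min_growth_frac: float = MIN_GROWTH_FRAC,
) -> bool:
    """Whether a series passes the burden and growth filters."""
    if len(series) < 2:
        return False
    return _scan_pair(series, min_volume, min_growth_frac) is not None


def growth_record(
    series: LesionSeries,
    min_volume: float = MIN_VOLUME_CM3,
    min_growth_frac: float = MIN_GROWTH_FRAC,
) -> GrowthRecord:
    """Specific growth rate and doubling time for an eligible series."""
    if len(series) < 2:
        raise ValueError(
            f"{series.patient_id}/{series.site.value}: needs >= 2 scans for a growth rate"
        )
    j = _scan_pair(series, min_volume, min_growth_frac)
    if j is None:
        v1 = series.volumes[0]
        if v1 < min_volume:
            why = f"first volume {v1:.4g} cm^3 below the {min_volume} cm^3 burden floor"
        else:
            why = f"no successive pair with >= {min_growth_frac:.0%} growth"
        raise ValueError(f"{series.patient_id}/{series.site.value}: ineligible ({why})")
    v1, v2 = series.volumes[j], series.volumes[j + 1]
    dt_months = (series.scan_days[j + 1] - series.scan_days[j]) / DAYS_PER_MONTH
    alpha = math.log(v2 / v1) / dt_months
    return GrowthRecord(
        patient_id=series.patient_id,
        site=series.site,
        v1=v1,
        v2=v2,
        dt_months=dt_months,
        alpha=alpha,
        tvdt_months=math.log(2.0) / alpha,
    )


def eligible_records(
    cohort: Cohort,
    min_volume: float = MIN_VOLUME_CM3,
    min_growth_frac: float = MIN_GROWTH_FRAC,
) -> list[GrowthRecord]:
    """Growth records for every eligible series in the cohort."""
    return [
        growth_record(s, min_volume, min_growth_frac)
        for s in cohort
        if eligible(s, min_volume, min_growth_frac)
    ]


def site_tvdt_summary(
    cohort: Cohort,
    min_volume: float = MIN_VOLUME_CM3,
    min_growth_frac: float = MIN_GROWTH_FRAC,
) -> dict[str, dict]:
    """Per-site count, median and IQR of doubling times (months)."""
    records = eligible_records(cohort, min_volume, min_growth_frac)
    out: dict[str, dict] = {}
    for site in Site:
        tvdts = np.array([r.tvdt_months for r in records if r.site == site])
        if tvdts.size == 0:
            warnings.warn(f"no eligible lesions for site {site.value}; omitted", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(tvdts, [25, 50, 75])
        out[site.value] = {
            "n": int(tvdts.size),
            "median_months": float(med),
            "iqr_months": (float(q1), float(q3)),
        }
    return out


def compare_groups(values_a, values_b) -> float:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum p-value.

    Exact null distribution for small samples (both n <= 25, no ties),
    normal approximation with continuity correction otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size <= 25 and b.size <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
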