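"""Time-to-metastasis and window-of-opportunity for dual-site cases.

For a patient with growing lesions in both the ovaries/pelvis and the
omentum, the site whose lesion is older at first scan (larger t1) is the
designated primary; the other initiated TTM = t1_primary - t1_secondary
months later. Screening could detect the primary once it crosses a
modality's detection threshold (ultrasound 0.5 cm^3, CA125 0.015 cm^3
equivalent), so the window of opportunity is

    WOO_modality = TTM - (time for the primary to reach the threshold).

A negative WOO means the metastasis is expected to have seeded before
the primary was detectable; it is reported as-is, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Site
from .gompertz import GompertzParams, time_to_volume, volume_at
from .nlme import TumorGrowthNLMEResults

__all__ = [
    "US_THRESHOLD_CM3",
    "CA125_THRESHOLD_CM3",
    "ScreeningThresholds",
    "CaseTiming",
    "case_timing",
    "dual_site_timings",
    "cohort_timing_summary",
]

US_THRESHOLD_CM3 = 0.5
CA125_THRESHOLD_CM3 = 0.015

#: Screens one year apart: a case whose whole pre-metastatic lifetime is
#: shorter than this cannot be caught by annual screening even at
#: single-cell detection resolution.
ANNUAL_SCREEN_MONTHS = 12.0


@dataclass(frozen=True)
class ScreeningThresholds:
    """Detection thresholds (cm^3) per screening modality."""

    us: float = US_THRESHOLD_CM3
    ca125: float = CA125_THRESHOLD_CM3

    def __post_init__(self) -> None:
        if not (0 < self.ca125 < self.us):
            raise ValueError(
                f"require 0 < ca125 < us thresholds, got ca125={self.ca125}, us={self.us}"
            )

    def as_dict(self) -> dict[str, float]:
        return {"us": self.us, "ca125": self.ca125}


@dataclass(frozen=True)
class CaseTiming:
    """Timing of one dual-site case, all in months from primary initiation."""

    patient_id: str
    t1_ov: float
    t1_om: float
    primary_site: Site
    ttm: float
    v_met: float  # primary volume at secondary initiation, cm^3
    detect_time: dict[str, float]  # modality -> months from primary initiation
    woo: dict[str, float]  # modality -> ttm - detect_time (may be negative)


def case_timing(
    patient_id: str,
    t1_ov: float,
    t1_om: float,
    params_primary: GompertzParams,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> CaseTiming:
    """Classify the primary site and compute TTM, detection times and WOO.

    The primary is the site with the larger lesion age at first scan;
    TTM is the difference of the two ages. Detection times invert the
    primary's Gompertz trajectory at each threshold.
    """
    if not (t1_ov > 0 and t1_om > 0):
        raise ValueError(f"both lesion ages must be positive, got {t1_ov}, {t1_om}")
    for name, thr in thresholds.as_dict().items():
        if thr >= params_primary.vinf:
            raise ValueError(
                f"{name} threshold {thr} cm^3 >= carrying capacity {params_primary.vinf}"
            )
    primary = Site.OVARY_PELVIS if t1_ov >= t1_om else Site.OMENTUM
    ttm = abs(t1_ov - t1_om)
    detect = {
        name: time_to_volume(params_primary, thr)
        for name, thr in thresholds.as_dict().items()
    }
    return CaseTiming(
        patient_id=patient_id,
        t1_ov=t1_ov,
        t1_om=t1_om,
        primary_site=primary,
        ttm=ttm,
        v_met=volume_at(params_primary, ttm),
        detect_time=detect,
        woo={name: ttm - t for name, t in detect.items()},
    )


def dual_site_timings(
    results_ov: TumorGrowthNLMEResults,
    results_om: TumorGrowthNLMEResults,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> list[CaseTiming]:
    """Case timings for every patient present in both site fits.

    Individual (empirical-Bayes) estimates supply each lesion's age t1
    and decay rate beta; the primary's own beta and its site's carrying
    capacity define the trajectory used for detection times.
    """
    if results_ov.law != "gompertz" or results_om.law != "gompertz":
        raise ValueError("dual-site timings require Gompertz fits for both sites")
    ind_ov = results_ov.individual_params
    ind_om = results_om.individual_params
    shared = [pid for pid in ind_ov.index if pid in ind_om.index]
    cases = []
    for pid in shared:
        t1_ov = float(ind_ov.loc[pid, "t1_months"])
        t1_om = float(ind_om.loc[pid, "t1_months"])
        if t1_ov >= t1_om:
            params = GompertzParams(
                vinf=results_ov.model.dataset.vinf,
                beta=float(ind_ov.loc[pid, "rate"]),
                v0=results_ov.model.dataset.v0,
            )
        else:
            params = GompertzParams(
                vinf=results_om.model.dataset.vinf,
                beta=float(ind_om.loc[pid, "rate"]),
                v0=results_om.model.dataset.v0,
            )
        cases.append(case_timing(pid, t1_ov, t1_om, params, thresholds))
    return cases


def cohort_timing_summary(
    cases: list[CaseTiming],
    annual_screen_months: float = ANNUAL_SCREEN_MONTHS,
) -> dict:
    """Summary of dual-site case timings.

    Counts cases whose time to metastasis is shorter than the screening
    interval (unreachable by annual screening even at single-cell
    resolution) and, per modality, cases whose metastasis precedes
    detectability (negative WOO); reports median/IQR of the positive
    windows.
    """
    if not cases:
        raise ValueError("no cases to summarise")
    ttms = np.array([c.ttm for c in cases])
    q1, med, q3 = np.percentile(ttms, [25, 50, 75])
    modalities = list(cases[0].woo)
    summary = {
        "n_cases": len(cases),
        "median_ttm_months": float(med),
        "iqr_ttm_months": (float(q1), float(q3)),
        "n_annual_miss": int(np.sum(ttms < annual_screen_months)),
        "n_pre_detect": {},
        "woo_months": {},
    }
    for m in modalities:
        woos = np.array([c.woo[m] for c in cases])
        summary["n_pre_detect"][m] = int(np.sum(woos < 0))
        pos = woos[woos > 0]
        if pos.size:
            pq1, pmed, pq3 = np.percentile(pos, [25, 50, 75])
            summary["woo_months"][m] = {
                "n_positive": int(pos.size),
                "median": float(pmed),
                "iqr": (float(pq1), float(pq3)),
            }
        else:
            summary["woo_months"][m] = {"n_positive": 0, "median": None, "iqr": None}
    return summary
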