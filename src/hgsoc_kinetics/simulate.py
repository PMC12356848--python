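"""Monte Carlo screening simulation over a virtual patient population.

Each virtual patient receives a primary disease site (omentum with
probability ``p_om``), a Gompertz decay rate beta drawn from that site's
fitted log-normal random-effects distribution, and a metastatic seeding
volume V_met resampled from an empirical pool (the Gompertz-estimated
primary volumes at secondary initiation in observed dual-site cases).
The carrying capacity per site stays fixed. Inverting the Gompertz
trajectory gives the time t_met for the primary to reach V_met and the
detection time at each screening threshold; the window of opportunity
is WOO = t_met - detection time, negative when the tumour seeds its
metastasis before it is detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Site
from .gompertz import SINGLE_CELL_CM3, GompertzParams, time_to_volume
from .nlme import TumorGrowthNLMEResults
from .timing import ScreeningThresholds

__all__ = ["BetaDistribution", "SimConfig", "SimResult", "simulate", "summarize", "config_from_fits"]


@dataclass(frozen=True)
class BetaDistribution:
    """Log-normal distribution of the Gompertz decay rate for one site."""

    log_mean: float  # (ln beta)^pop
    log_sd: float  # sqrt of the random-effects variance of ln beta

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(self.log_mean, self.log_sd, size=n))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the virtual screening population."""

    beta_dist: dict[str, BetaDistribution]  # site value -> distribution
    vinf: dict[str, float]  # site value -> carrying capacity, cm^3
    v_met_pool: tuple[float, ...]  # empirical metastatic seeding volumes, cm^3
    n_patients: int = 10_000
    p_om: float = 0.36
    thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    v0: float = SINGLE_CELL_CM3

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_om <= 1.0):
            raise ValueError(f"p_om must be in [0, 1], got {self.p_om}")
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not self.v_met_pool:
            raise ValueError("v_met_pool must be non-empty")
        vmin = min(self.vinf.values())
        for v in self.v_met_pool:
            if not (self.v0 < v < vmin):
                raise ValueError(
                    f"v_met {v} cm^3 outside (v0, min vinf) = ({self.v0}, {vmin})"
                )
        for site in (Site.OVARY_PELVIS.value, Site.OMENTUM.value):
            if site not in self.beta_dist or site not in self.vinf:
                raise ValueError(f"beta_dist and vinf must cover site {site!r}")


@dataclass(frozen=True)
class SimResult:
    """Per-patient outcomes of one simulation run."""

    patients: pd.DataFrame  # primary_site, beta, v_met, t_met, detect_*, woo_*
    config: SimConfig
    seed: int

    def __len__(self) -> int:
        return len(self.patients)


def config_from_fits(
    results_ov: TumorGrowthNLMEResults,
    results_om: TumorGrowthNLMEResults,
    v_met_pool,
    n_patients: int = 10_000,
    p_om: float = 0.36,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> SimConfig:
    """Derive a simulation config from per-site Gompertz population fits.

    The decay-rate distribution of each site is log-normal with log-mean
    (ln beta)^pop and log-variance the fitted random-effects variance of
    ln beta; carrying capacities are taken from the fits' transform.
    """
    def dist(res: TumorGrowthNLMEResults) -> BetaDistribution:
        if res.law != "gompertz":
            raise ValueError("simulation config requires Gompertz fits")
        return BetaDistribution(
            log_mean=float(res.params[1]), log_sd=float(np.sqrt(max(res.D[1, 1], 0.0)))
        )

    return SimConfig(
        beta_dist={
            Site.OVARY_PELVIS.value: dist(results_ov),
            Site.OMENTUM.value: dist(results_om),
        },
        vinf={
            Site.OVARY_PELVIS.value: float(results_ov.model.dataset.vinf),
            Site.OMENTUM.value: float(results_om.model.dataset.vinf),
        },
        v_met_pool=tuple(float(v) for v in v_met_pool),
        n_patients=n_patients,
        p_om=p_om,
        thresholds=thresholds,
    )


def simulate(config: SimConfig, seed: int) -> SimResult:
    """Run the virtual-population screening simulation.

    Fully reproducible for a fixed seed. A sampled V_met below a
    detection threshold simply yields a negative window for that
    modality (metastasis precedes detectability); it is never an error.
    """
    rng = np.random.default_rng(seed)
    n = config.n_patients
    is_om = rng.random(n) < config.p_om
    sites = np.where(is_om, Site.OMENTUM.value, Site.OVARY_PELVIS.value)
    betas = np.empty(n)
    for site in (Site.OVARY_PELVIS.value, Site.OMENTUM.value):
        idx = sites == site
        betas[idx] = config.beta_dist[site].sample(rng, int(idx.sum()))
    v_met = rng.choice(np.asarray(config.v_met_pool, dtype=float), size=n, replace=True)

    t_met = np.empty(n)
    detect = {m: np.empty(n) for m in config.thresholds.as_dict()}
    thr = config.thresholds.as_dict()
    for i in range(n):
        p = GompertzParams(vinf=config.vinf[sites[i]], beta=betas[i], v0=config.v0)
        t_met[i] = time_to_volume(p, v_met[i])
        for m, v in thr.items():
            detect[m][i] = time_to_volume(p, v)

    df = pd.DataFrame(
        {
            "primary_site": sites,
            "beta": betas,
            "v_met_cm3": v_met,
            "t_met_months": t_met,
        }
    )
    for m in thr:
        df[f"detect_{m}_months"] = detect[m]
        df[f"woo_{m}_months"] = t_met - detect[m]
    return SimResult(patients=df, config=config, seed=seed)


def summarize(result: SimResult) -> dict:
    """Detect-before-metastasis fractions and positive-WOO quantiles.

    The fraction per modality counts patients with WOO > 0; the median
    and IQR of the window are computed over those patients only. When no
    patient has a positive window, the median/IQR are reported as
    absent (None).
    """
    if len(result) == 0:
        raise ValueError("empty simulation result")
    out: dict = {"n_patients": len(result), "seed": result.seed, "modalities": {}}
    for m in result.config.thresholds.as_dict():
        woo = result.patients[f"woo_{m}_months"].to_numpy()
        pos = woo[woo > 0]
        block: dict = {"fraction_detect_before_met": float(pos.size / woo.size)}
        if pos.size:
            q1, med, q3 = np.percentile(pos, [25, 50, 75])
            block["median_woo_months"] = float(med)
            block["iqr_woo_months"] = (float(q1), float(q3))
        else:
            block["median_woo_months"] = None
            block["iqr_woo_months"] = None
        out["modalities"][m] = block
    return out
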