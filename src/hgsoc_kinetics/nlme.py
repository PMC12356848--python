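"""Population back-projection of lesion initiation times.

A nonlinear mixed-effects (NLME) model estimates, from serial lesion
volumes, how long before the first scan each lesion initiated. Both
growth laws (Gompertz and exponential) become linear in time after the
observation transform (see :mod:`.gompertz`), so each subject's
transformed observations follow

    y_j = exp(theta_1) + exp(theta_2) * dt_j + lambda * eps_j

with theta = (ln(rate * t1), ln(rate)), dt_j the interval from the
subject's first scan (dt_1 = 0), and Gaussian random effects
theta_i = theta_pop + N(0, D) across subjects. The log parametrisation
guarantees positive rates and ages. Estimation maximises a linearised
approximation of the marginal log-likelihood by alternating between
penalised nonlinear least squares for the per-subject random effects
(empirical-Bayes modes) and maximum likelihood for (theta_pop, D,
lambda) on the model linearised about those modes — the classic
alternating scheme for NLME estimation. All per-subject computations
are batched across subjects (grouped by series length) so a cohort fit
takes well under a second.

The quantity of interest is the population lesion age at first scan,
t1_pop = exp(theta_1_pop - theta_2_pop), with a 95% CI from the delta
method applied on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import Cohort, Site
from .gompertz import (
    DAYS_PER_MONTH,
    SINGLE_CELL_CM3,
    ExponentialParams,
    GompertzParams,
    exponential_y,
    gompertz_y,
)
from .growth import MIN_GROWTH_FRAC, MIN_VOLUME_CM3, eligible

__all__ = [
    "SubjectSeries",
    "TransformedDataset",
    "PopulationAge",
    "ConvergenceError",
    "auto_vinf",
    "build_transformed",
    "TumorGrowthNLME",
    "TumorGrowthNLMEResults",
]

#: Headroom applied to the per-site maximum observed volume when the
#: carrying capacity is derived from the data ("auto"): the observation
#: transform diverges exactly at Vinf, so the largest lesion must sit
#: strictly inside the domain.
VINF_HEADROOM = 1.05

_LOG_SCALE_MIN = math.log(1e-6)
_LOG_SCALE_MAX = math.log(1e3)


class ConvergenceError(RuntimeError):
    """Raised when the alternating NLME algorithm fails to converge.

    Carries the last iterate on the ``results`` attribute.
    """

    def __init__(self, message: str, results: "TumorGrowthNLMEResults | None" = None):
        super().__init__(message)
        self.results = results


@dataclass(frozen=True)
class SubjectSeries:
    """Transformed observations of one subject: (dt_j, y_j), dt_1 = 0."""

    subject_id: str
    dt: np.ndarray  # months from first scan
    y: np.ndarray


@dataclass(frozen=True)
class TransformedDataset:
    """Per-subject transformed observations ready for the NLME fit."""

    subjects: tuple[SubjectSeries, ...]
    law: str  # 'gompertz' | 'exponential'
    site: Site | None
    v0: float
    vinf: float | None  # None for exponential

    def __post_init__(self) -> None:
        if self.law not in ("gompertz", "exponential"):
            raise ValueError(f"law must be 'gompertz' or 'exponential', got {self.law!r}")
        for s in self.subjects:
            if len(s.dt) < 2:
                raise ValueError(f"subject {s.subject_id}: needs >= 2 observations")
            if s.dt[0] != 0.0:
                raise ValueError(f"subject {s.subject_id}: first observation must have dt = 0")

    @property
    def k(self) -> float | None:
        return None if self.vinf is None else math.log(self.vinf / self.v0)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class PopulationAge:
    """Population lesion age at first scan (months) with 95% CI."""

    t1_pop: float
    ci95: tuple[float, float]


def auto_vinf(cohort: Cohort, site: Site | str, headroom: float = VINF_HEADROOM) -> float:
    """Carrying capacity from the data: per-site maximum observed volume.

    A small headroom factor keeps the largest lesion strictly inside the
    transform domain (the transform diverges at Vinf itself).
    """
    site = Site.parse(site) if not isinstance(site, Site) else site
    vols = [v for s in cohort.by_site(site) for v in s.volumes]
    if not vols:
        raise ValueError(f"no measurements for site {site.value}")
    return max(vols) * headroom


def build_transformed(
    cohort: Cohort,
    site: Site | str,
    law: str = "gompertz",
    vinf: float | str = "auto",
    v0: float = SINGLE_CELL_CM3,
    min_volume: float = MIN_VOLUME_CM3,
    min_growth_frac: float = MIN_GROWTH_FRAC,
) -> TransformedDataset:
    """Transform the eligible series of one site for the population fit.

    Only series passing the growth/burden filters enter the fit. Times
    are months from each subject's first scan; observations are the
    law's linearising transform of the measured volumes.
    """
    site = Site.parse(site) if not isinstance(site, Site) else site
    series = [s for s in cohort.by_site(site) if eligible(s, min_volume, min_growth_frac)]
    if not series:
        raise ValueError(f"no eligible series for site {site.value}")
    if law == "gompertz":
        if vinf == "auto":
            vinf_val = auto_vinf(cohort, site)
        else:
            vinf_val = float(vinf)
        params = GompertzParams(vinf=vinf_val, beta=1.0, v0=v0)  # beta unused by the transform
        subjects = []
        for s in series:
            for v in s.volumes:
                if v >= vinf_val:
                    raise ValueError(
                        f"subject {s.patient_id}: volume {v} cm^3 >= Vinf {vinf_val} cm^3 "
                        f"(outside the Gompertz transform domain)"
                    )
            y = np.array([gompertz_y(v, params) for v in s.volumes])
            dt = (np.asarray(s.scan_days) - s.scan_days[0]) / DAYS_PER_MONTH
            subjects.append(SubjectSeries(s.patient_id, dt, y))
        return TransformedDataset(tuple(subjects), "gompertz", site, v0, vinf_val)
    elif law == "exponential":
        ep = ExponentialParams(alpha=1.0, v0=v0)  # alpha unused by the transform
        subjects = []
        for s in series:
            y = np.array([exponential_y(v, ep) for v in s.volumes])
            dt = (np.asarray(s.scan_days) - s.scan_days[0]) / DAYS_PER_MONTH
            subjects.append(SubjectSeries(s.patient_id, dt, y))
        return TransformedDataset(tuple(subjects), "exponential", site, v0, None)
    raise ValueError(f"unknown law {law!r}")


# ---------------------------------------------------------------------------
# model internals (batched over subjects; phi has shape (g, 2))


def _f_batch(phi: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """Mean response exp(phi1) + exp(phi2) * dt, batched: (g, m)."""
    return np.exp(phi[:, :1]) + np.exp(phi[:, 1:2]) * dt


def _jac_batch(phi: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """d f / d phi, batched: (g, m, 2)."""
    J = np.empty(dt.shape + (2,))
    J[..., 0] = np.exp(phi[:, :1]) * np.ones_like(dt)
    J[..., 1] = np.exp(phi[:, 1:2]) * dt
    return J


def _chol_from_eta(eta: np.ndarray, diagonal: bool) -> tuple[np.ndarray, float]:
    """(L, lambda) from the unconstrained vector eta.

    Full D: eta = (log L11, L21, log L22, log lambda); diagonal D drops L21.
    """
    if diagonal:
        L = np.diag([math.exp(eta[0]), math.exp(eta[1])])
        lam = math.exp(eta[2])
    else:
        L = np.array([[math.exp(eta[0]), 0.0], [eta[1], math.exp(eta[2])]])
        lam = math.exp(eta[3])
    return L, lam


def _marginal_cov(X: np.ndarray, D: np.ndarray, lam: float) -> np.ndarray:
    """Sigma = X D X' + lambda^2 I per subject, with a tiny relative ridge.

    ``X`` has shape (g, m, 2); the ridge (1e-12 of the mean diagonal)
    keeps the Cholesky stable in the degenerate limit where both D and
    lambda collapse to their lower bounds; it is far below estimation
    precision otherwise.
    """
    g, m, _ = X.shape
    Sigma = np.einsum("gmi,ij,gnj->gmn", X, D, X) + lam**2 * np.eye(m)
    tr = np.einsum("gmm->g", Sigma) / m
    return Sigma + (1e-12 * np.maximum(tr, 1e-30))[:, None, None] * np.eye(m)


def _dD_basis(L: np.ndarray, diagonal: bool) -> list[np.ndarray]:
    """dD/d eta_k for the Cholesky parameters (log-diag, raw off-diag)."""
    dLs = [np.array([[L[0, 0], 0.0], [0.0, 0.0]])]
    if not diagonal:
        dLs.append(np.array([[0.0, 0.0], [1.0, 0.0]]))
    dLs.append(np.array([[0.0, 0.0], [0.0, L[1, 1]]]))
    return [dL @ L.T + L @ dL.T for dL in dLs]


class TumorGrowthNLME:
    """Nonlinear mixed-effects model for lesion growth back-projection.

    Parameters
    ----------
    dataset : TransformedDataset
        Per-subject transformed observations, e.g. from
        :func:`build_transformed`. Each subject needs >= 2 observations
        with the first at dt = 0; at least 3 subjects are required for
        the random-effects covariance to be identifiable.

    Examples
    --------
    >>> model = TumorGrowthNLME.from_cohort(cohort, site="ovary_pelvis")
    >>> res = model.fit()
    >>> res.population_age()           # doctest: +SKIP
    PopulationAge(t1_pop=20.4, ci95=(13.6, 30.6))
    """

    def __init__(self, dataset: TransformedDataset):
        if dataset.n_subjects < 3:
            raise ValueError(
                f"need >= 3 subjects to identify the random-effects covariance, "
                f"got {dataset.n_subjects}"
            )
        self.dataset = dataset
        self.subject_ids = [s.subject_id for s in dataset.subjects]
        self.n_obs = sum(len(s.dt) for s in dataset.subjects)
        # group subjects by series length for batched linear algebra
        by_m: dict[int, list[int]] = {}
        for i, s in enumerate(dataset.subjects):
            by_m.setdefault(len(s.dt), []).append(i)
        self._groups = []
        for m, idxs in sorted(by_m.items()):
            dt = np.array([dataset.subjects[i].dt for i in idxs], dtype=float)
            y = np.array([dataset.subjects[i].y for i in idxs], dtype=float)
            self._groups.append((np.array(idxs), dt, y))

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        site: Site | str,
        law: str = "gompertz",
        vinf: float | str = "auto",
        v0: float = SINGLE_CELL_CM3,
        min_volume: float = MIN_VOLUME_CM3,
        min_growth_frac: float = MIN_GROWTH_FRAC,
    ) -> "TumorGrowthNLME":
        """Build the model from a cohort, applying the eligibility filters."""
        return cls(
            build_transformed(cohort, site, law, vinf, v0, min_volume, min_growth_frac)
        )

    # -- initial values ----------------------------------------------------

    def _init_values(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Per-subject OLS on (dt, y) -> logs -> moment estimates.

        With dt_1 = 0 the OLS intercept is y at the first scan and the
        slope the growth rate of the transformed observation; both are
        positive for growing lesions and clipped away from zero for
        numerical safety.
        """
        n = len(self.subject_ids)
        thetas = np.empty((n, 2))
        resid_var = []
        for idxs, dt, y in self._groups:
            for k, i in enumerate(idxs):
                A = np.column_stack([np.ones_like(dt[k]), dt[k]])
                coef, res, *_ = np.linalg.lstsq(A, y[k], rcond=None)
                thetas[i] = [math.log(max(coef[0], 1e-8)), math.log(max(coef[1], 1e-8))]
                if len(dt[k]) > 2 and len(res):
                    resid_var.append(res[0] / (len(dt[k]) - 2))
        theta_pop = thetas.mean(axis=0)
        D0 = np.cov(thetas.T) if n > 1 else np.eye(2)
        D0 = np.atleast_2d(D0) + 1e-6 * np.eye(2)
        if resid_var:
            lam0 = math.sqrt(max(float(np.mean(resid_var)), 1e-10))
        else:
            # two obs per subject leave no residual: start from a small
            # fraction of the observation scale
            scale = float(np.mean([np.abs(y).mean() for _, _, y in self._groups]))
            lam0 = max(0.02 * scale, 1e-4)
        return theta_pop, D0, lam0

    # -- penalised nonlinear least squares for random effects --------------

    def _eb_modes(self, theta_pop: np.ndarray, D: np.ndarray, lam: float) -> np.ndarray:
        """Empirical-Bayes modes b_i of the random effects.

        Minimises ||(y - f(theta_pop + b))/lambda||^2 + b' D^{-1} b per
        subject (the posterior mode under the Gaussian prior), by
        batched Gauss-Newton with step halving.
        """
        Dinv = np.linalg.inv(D + 1e-12 * np.eye(2))
        lam2 = max(lam, 1e-8) ** 2
        modes = np.zeros((len(self.subject_ids), 2))

        def objective(b, dt, y):
            r = y - _f_batch(theta_pop[None, :] + b, dt)
            return np.einsum("gm,gm->g", r, r) / lam2 + np.einsum(
                "gi,ij,gj->g", b, Dinv, b
            )

        for idxs, dt, y in self._groups:
            b = np.zeros((len(idxs), 2))
            obj = objective(b, dt, y)
            for _ in range(100):
                phi = theta_pop[None, :] + b
                r = y - _f_batch(phi, dt)
                J = _jac_batch(phi, dt)
                grad = np.einsum("gmi,gm->gi", J, r) / lam2 - b @ Dinv.T
                H = np.einsum("gmi,gmj->gij", J, J) / lam2 + Dinv[None, :, :]
                step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
                # backtrack per subject until the penalised objective drops
                scale = np.ones(len(idxs))
                for _half in range(25):
                    cand = b + scale[:, None] * step
                    new_obj = objective(cand, dt, y)
                    worse = new_obj > obj + 1e-12
                    if not worse.any():
                        break
                    scale[worse] *= 0.5
                b = b + scale[:, None] * step
                new_obj = objective(b, dt, y)
                if np.max(np.abs(scale[:, None] * step)) < 1e-12:
                    obj = new_obj
                    break
                obj = new_obj
            modes[idxs] = b
        return modes

    # -- linearised marginal likelihood -------------------------------------

    def _linearize(self, theta_pop: np.ndarray, modes: np.ndarray):
        """First-order expansion about phi_i = theta_pop + b_i.

        Returns per-group (w, X) with X = Z the Jacobian and w the
        working observations y - f(phi) + X phi, so that
        w ~ N(X theta_pop + Z b, lambda^2 I) under the expansion.
        """
        out = []
        for idxs, dt, y in self._groups:
            phi = theta_pop[None, :] + modes[idxs]
            X = _jac_batch(phi, dt)
            w = y - _f_batch(phi, dt) + np.einsum("gmi,gi->gm", X, phi)
            out.append((w, X))
        return out

    @staticmethod
    def _profile_neg2ll_grad(eta, groups, diagonal):
        """Profiled -2 log-likelihood of the linearised model + gradient.

        theta is concentrated out by GLS; by the envelope theorem the
        gradient in the variance parameters only needs the partials of
        Sigma: for each Cholesky parameter of D,
        d(-2ll) = tr(dD (A - U)) with A = sum_i X' Sigma^{-1} X and
        U = sum_i u u', u = X' Sigma^{-1} r; for log lambda,
        d(-2ll) = 2 lambda^2 (sum_i tr Sigma^{-1} - ||Sigma^{-1} r||^2).
        """
        eta = np.asarray(eta, dtype=float)
        L, lam = _chol_from_eta(eta, diagonal)
        D = L @ L.T
        n_eta = len(eta)
        A = np.zeros((2, 2))
        c = np.zeros(2)
        sww = 0.0
        logdet = 0.0
        cache = []
        for w, X in groups:
            Sigma = _marginal_cov(X, D, lam)
            try:
                ch = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros(n_eta)
            logdet += 2.0 * float(np.sum(np.log(np.einsum("gmm->gm", ch))))
            Sinv = np.linalg.inv(Sigma)
            Siw = np.einsum("gmn,gn->gm", Sinv, w)
            A += np.einsum("gmi,gmn,gnj->ij", X, Sinv, X)
            c += np.einsum("gmi,gm->i", X, Siw)
            sww += float(np.einsum("gm,gm->", w, Siw))
            cache.append((w, X, Sinv))
        try:
            theta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(n_eta)
        obj = logdet + sww - float(c @ theta)

        U = np.zeros((2, 2))
        tr_sinv = 0.0
        srsr = 0.0
        for w, X, Sinv in cache:
            r = w - np.einsum("gmi,i->gm", X, theta)
            Sr = np.einsum("gmn,gn->gm", Sinv, r)
            u = np.einsum("gmi,gm->gi", X, Sr)
            U += np.einsum("gi,gj->ij", u, u)
            tr_sinv += float(np.einsum("gmm->", Sinv))
            srsr += float(np.einsum("gm,gm->", Sr, Sr))
        grad = np.empty(n_eta)
        for k, dD in enumerate(_dD_basis(L, diagonal)):
            grad[k] = float(np.sum(dD * (A - U)))
        grad[-1] = 2.0 * lam**2 * (tr_sinv - srsr)
        return obj, grad

    def _self_consistent_neg2ll(self, z, diagonal):
        """Linearised -2 log-likelihood as a direct function of (theta, eta).

        Unlike the alternating scheme, the EB modes and the expansion
        point are recomputed inside the objective, so this is a single
        fixed function suitable for derivative-free minimisation.
        """
        theta = np.asarray(z[:2], dtype=float)
        eta = np.asarray(z[2:], dtype=float)
        L, lam = _chol_from_eta(eta, diagonal)
        D = L @ L.T
        modes = self._eb_modes(theta, D, lam)
        groups = self._linearize(theta, modes)
        total = 0.0
        for w, X in groups:
            Sigma = _marginal_cov(X, D, lam)
            try:
                ch = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return 1e12
            r = w - np.einsum("gmi,i->gm", X, theta)
            Sr = np.linalg.solve(Sigma, r[:, :, None])[:, :, 0]
            total += 2.0 * float(np.sum(np.log(np.einsum("gmm->gm", ch)))) + float(
                np.einsum("gm,gm->", r, Sr)
            )
        return total

    @staticmethod
    def _gls(eta, groups, diagonal):
        """GLS fixed effects and their covariance at the given (D, lambda)."""
        L, lam = _chol_from_eta(np.asarray(eta, dtype=float), diagonal)
        D = L @ L.T
        A = np.zeros((2, 2))
        c = np.zeros(2)
        for w, X in groups:
            Sinv = np.linalg.inv(_marginal_cov(X, D, lam))
            A += np.einsum("gmi,gmn,gnj->ij", X, Sinv, X)
            c += np.einsum("gmi,gmn,gn->i", X, Sinv, w)
        cov = np.linalg.inv(A)
        return cov @ c, cov, D, lam

    # -- main driver ---------------------------------------------------------

    def fit(
        self,
        diagonal_d: bool = False,
        maxiter: int = 200,
        obj_tol: float = 1e-8,
        param_tol: float = 1e-6,
    ) -> "TumorGrowthNLMEResults":
        """Fit by alternating EB-mode estimation and linearised ML.

        Parameters
        ----------
        diagonal_d : bool
            Restrict the random-effects covariance D to a diagonal
            matrix (full 2x2 via its Cholesky factor by default).
        maxiter : int
            Maximum outer (relinearisation) iterations.
        obj_tol, param_tol : float
            Convergence: relative change of the linearised -2
            log-likelihood below ``obj_tol`` and fixed-effect change
            below ``param_tol``.
        """
        theta, D, lam = self._init_values()
        modes = self._eb_modes(theta, D, lam)

        def eta_from(D, lam, diagonal):
            Lc = np.linalg.cholesky(D + 1e-12 * np.eye(2))
            llam = min(max(math.log(lam), _LOG_SCALE_MIN), _LOG_SCALE_MAX)
            if diagonal:
                return np.array(
                    [math.log(max(Lc[0, 0], 1e-8)), math.log(max(Lc[1, 1], 1e-8)), llam]
                )
            return np.array(
                [math.log(max(Lc[0, 0], 1e-8)), Lc[1, 0], math.log(max(Lc[1, 1], 1e-8)), llam]
            )

        if diagonal_d:
            bounds = [(_LOG_SCALE_MIN, _LOG_SCALE_MAX)] * 3
        else:
            bounds = [
                (_LOG_SCALE_MIN, _LOG_SCALE_MAX),
                (-50.0, 50.0),
                (_LOG_SCALE_MIN, _LOG_SCALE_MAX),
                (_LOG_SCALE_MIN, _LOG_SCALE_MAX),
            ]
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        prev_obj = np.inf
        converged = False
        n_iter = 0
        obj = np.inf
        eta = eta_from(D, lam, diagonal_d)
        cov_theta = np.full((2, 2), np.nan)
        groups = None
        # step damping: the relinearisation map can settle into a
        # two-cycle; when successive fixed-effect steps reverse
        # direction, shrink the step along the new update and let it
        # recover once steps align again
        gamma = 1.0
        gamma_cap = 1.0  # sticky: each reversal permanently lowers the ceiling
        prev_delta = None
        for n_iter in range(1, maxiter + 1):
            groups = self._linearize(theta, modes)
            sol = optimize.minimize(
                self._profile_neg2ll_grad,
                np.clip(eta, lo, hi),
                args=(groups, diagonal_d),
                method="L-BFGS-B",
                jac=True,
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
            eta = sol.x
            obj = float(sol.fun)
            theta_new, cov_theta, D, lam = self._gls(eta, groups, diagonal_d)
            delta = theta_new - theta
            dtheta = float(np.max(np.abs(delta)))
            modes_new = self._eb_modes(theta + delta, D, lam)
            full_delta = np.concatenate([delta, (modes_new - modes).ravel()])
            if prev_delta is not None and float(full_delta @ prev_delta) < 0.0:
                gamma = max(0.5 * gamma, 0.05)
                gamma_cap = max(0.5 * gamma_cap, 0.1)
            else:
                gamma = min(1.2 * gamma, gamma_cap)
            prev_delta = full_delta
            theta = theta + gamma * delta
            # damp the linearisation point too: the oscillation, when it
            # occurs, lives in the (modes, variance) subsystem
            modes = modes + gamma * (modes_new - modes)
            rel = abs(prev_obj - obj) / max(abs(obj), 1.0)
            if rel < obj_tol and dtheta < param_tol:
                converged = True
                break
            prev_obj = obj

        if not converged:
            # the alternating map can limit-cycle between two nearly
            # equivalent (D, lambda) decompositions; fall back to direct
            # minimisation of the self-consistent linearised objective in
            # (theta, eta) jointly, which is a fixed smooth function
            z0 = np.concatenate([theta, np.clip(eta, lo, hi)])
            z_bounds = [(-30.0, 30.0)] * 2 + bounds
            sol = optimize.minimize(
                self._self_consistent_neg2ll,
                z0,
                args=(diagonal_d,),
                method="Nelder-Mead",
                bounds=z_bounds,
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 6000, "maxfev": 6000},
            )
            if sol.status == 0:
                converged = True
                theta, eta = sol.x[:2], sol.x[2:]
                obj = float(sol.fun)
                L, lam = _chol_from_eta(eta, diagonal_d)
                D = L @ L.T
                modes = self._eb_modes(theta, D, lam)
                groups = self._linearize(theta, modes)
                _, cov_theta, D, lam = self._gls(eta, groups, diagonal_d)

        loglik = -0.5 * (obj + self.n_obs * math.log(2.0 * math.pi))
        results = TumorGrowthNLMEResults(
            model=self,
            params=theta,
            cov_params_matrix=cov_theta,
            D=D,
            lam=lam,
            random_effects=modes,
            loglik=loglik,
            converged=converged,
            n_iter=n_iter,
            _linearization=groups,
            _diagonal_d=diagonal_d,
        )
        if not converged:
            raise ConvergenceError(
                f"NLME did not converge in {maxiter} outer iterations",
                results=results,
            )
        return results


@dataclass
class TumorGrowthNLMEResults:
    """Results of a fitted lesion-growth NLME.

    Attributes
    ----------
    params : ndarray, shape (2,)
        Fixed effects (theta_pop): [ln(rate * t1), ln(rate)] — i.e.
        (ln beta*t1, ln beta) for the Gompertz law, (ln alpha*t1,
        ln alpha) for the exponential law.
    cov_params_matrix : ndarray, shape (2, 2)
        Covariance of the fixed effects from the linearised fit.
    D : ndarray, shape (2, 2)
        Random-effects covariance.
    lam : float
        Residual scale of the transformed observations.
    random_effects : ndarray, shape (n_subjects, 2)
        Empirical-Bayes modes b_i.
    """

    model: TumorGrowthNLME
    params: np.ndarray
    cov_params_matrix: np.ndarray
    D: np.ndarray
    lam: float
    random_effects: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    _linearization: list
    _diagonal_d: bool

    param_names = ("ln_rate_t1", "ln_rate")

    @property
    def law(self) -> str:
        return self.model.dataset.law

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params_matrix))

    @property
    def n_subjects(self) -> int:
        return len(self.model.subject_ids)

    @property
    def individual_params(self) -> pd.DataFrame:
        """Per-subject theta_i = theta_pop + b_i plus derived rate and t1."""
        theta_i = self.params[None, :] + self.random_effects
        df = pd.DataFrame(theta_i, columns=list(self.param_names), index=self.model.subject_ids)
        df.index.name = "subject_id"
        df["rate"] = np.exp(df["ln_rate"])
        df["t1_months"] = np.exp(df["ln_rate_t1"] - df["ln_rate"])
        return df

    def population_age(self) -> PopulationAge:
        """Population lesion age t1_pop = exp(theta_1 - theta_2), 95% CI.

        The CI uses the delta method on g = theta_1 - theta_2 (so on the
        log-age scale) and is then exponentiated, guaranteeing positive
        bounds: se(g)^2 = var(theta_1) + var(theta_2) - 2 cov.
        """
        g = float(self.params[0] - self.params[1])
        V = self.cov_params_matrix
        var_g = float(V[0, 0] + V[1, 1] - 2.0 * V[0, 1])
        se_g = math.sqrt(max(var_g, 0.0))
        return PopulationAge(
            t1_pop=math.exp(g),
            ci95=(math.exp(g - 1.96 * se_g), math.exp(g + 1.96 * se_g)),
        )

    def individual_ages(self) -> pd.Series:
        """Per-subject lesion age at first scan, t1_i = exp(theta1_i - theta2_i)."""
        df = self.individual_params
        return df["t1_months"].rename("t1_months")

    def linearized_neg2ll(self, theta=None, D=None, lam=None) -> float:
        """-2 log-likelihood of the final linearised model at given params.

        Defaults to the fitted values; useful for checking local
        optimality of the estimate.
        """
        theta = self.params if theta is None else np.asarray(theta, dtype=float)
        D = self.D if D is None else np.asarray(D, dtype=float)
        lam = self.lam if lam is None else float(lam)
        total = 0.0
        for w, X in self._linearization:
            Sigma = _marginal_cov(X, D, lam)
            ch = np.linalg.cholesky(Sigma)
            r = w - np.einsum("gmi,i->gm", X, theta)
            Sr = np.linalg.solve(Sigma, r[:, :, None])[:, :, 0]
            total += 2.0 * float(np.sum(np.log(np.einsum("gmm->gm", ch)))) + float(
                np.einsum("gm,gm->", r, Sr)
            )
        return total

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        age = self.population_age()
        rate = math.exp(self.params[1])
        lines = [
            "Lesion growth NLME results",
            "=" * 58,
            f"growth law:        {self.law}",
            f"site:              {self.model.dataset.site.value if self.model.dataset.site else '-'}",
            f"subjects:          {self.n_subjects}",
            f"observations:      {self.model.n_obs}",
            f"converged:         {self.converged} ({self.n_iter} outer iterations)",
            f"log-likelihood:    {self.loglik:.4f}  (linearised)",
            "-" * 58,
            f"{'param':<14}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<14}{est:>12.4f}{se:>12.4f}")
        lines += [
            "-" * 58,
            f"rate (per month):  {rate:.4f}",
            f"t1_pop (months):   {age.t1_pop:.2f}  95% CI [{age.ci95[0]:.2f}, {age.ci95[1]:.2f}]",
            f"residual scale:    {self.lam:.4g}",
            "random-effects covariance D:",
            f"  [{self.D[0,0]:.4g}, {self.D[0,1]:.4g}; {self.D[1,0]:.4g}, {self.D[1,1]:.4g}]",
            "=" * 58,
        ]
        return "\n".join(lines)
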