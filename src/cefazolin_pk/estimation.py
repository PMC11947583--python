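"""Population fitting by maximum marginal likelihood (Laplace approximation).

The hierarchical model: subject-level structural parameters are typical
values (after covariate scaling) times independent log-normal random effects
on CL, V1, Q, V2 and Bmax; relative recovery carries a subject-level and a
per-catheter log-normal effect multiplying the obesity-group typical value.
Observations in all four streams follow a proportional residual model
implemented as log-normal (Gaussian on log concentration with log-scale SD
``sigma``), which matches the stated CV exactly and guarantees positive
support even at a 50%+ CV.

The calibrated catheter recovery is a fraction: the model soft-caps it
below 1 (the same smooth cap the data generator applies). The per-interval
(intracatheter) effect is a microdialysis sampling phenomenon with exactly
one measurement per interval; because a microdialysate prediction is
proportional to recovery, that effect is log-additive and folds exactly
into the microdialysate residual variance, so the fitted microdialysate
sigma is the total per-record spread (assay error plus per-sample recovery
scatter). Retrodialysis calibration samples carry their own residual error
only.

The marginal likelihood integrates the subject-level random effects by a
Laplace approximation at the empirical-Bayes mode with a Gauss-Newton
Hessian; plain Monte Carlo integration over the prior is available as a
verification fallback. The inner mode search is a damped Newton iteration
run simultaneously for all subjects that share an observation design, with
exact gradients obtained by complex-step differentiation through the
closed-form kinetic solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .dataset import subject_regimen_events, validate_dataset
from .kinetics import BiexponentialSolution, DosingRegimen, bind_total
from .params import ScalingReference
from .simulate import omega_to_cv
from .study import soft_cap_recovery

logger = logging.getLogger(__name__)

_PRED_SMOOTH_EPS = 0.1   # mg/L; scale of the smooth positivity floor
_MAX_ETA_STEP = 2.0      # trust-region cap on one inner Newton step (log scale)
_LOG2PI = np.log(2.0 * np.pi)

def _smooth_floor(x):
    """Positive part with bounded, complex-step-safe gradients."""
    return 0.5 * (x + np.sqrt(x * x + _PRED_SMOOTH_EPS**2))


def _underflow_guard(x):
    """Keep log() finite when exponentials underflow at extreme parameters."""
    return 0.5 * (x + np.sqrt(x * x + 1e-12))


#: random-effect slots: five structural, subject-level RR, two catheter effects
ETA_NAMES = ("cl", "v1", "q", "v2", "bmax", "rr", "cath1", "cath2")

PARAM_NAMES = (
    "cl", "v1_ref", "q_ref", "v2_ref", "r_frac", "bmax", "kd", "tf",
    "rr_obese", "rr_nonobese",
    "omega_cl", "omega_v1", "omega_q", "omega_v2", "omega_bmax",
    "omega_rr", "omega_cath",
    "sigma_plasma", "sigma_microdialysate", "sigma_retrodialysate",
)

_LOGIT_PARAMS = {"r_frac", "tf", "rr_obese", "rr_nonobese"}

_BOUNDS_NATURAL = {
    "cl": (0.5, 500.0),
    "v1_ref": (1.0, 1000.0),
    "q_ref": (1.0, 1000.0),
    "v2_ref": (1.0, 1000.0),
    "bmax": (10.0, 5000.0),
    "kd": (0.5, 2000.0),
}
_LOGIT_BOUND = 7.0
_OMEGA_BOUNDS = (0.01, 1.5)   # log-scale SD
_SIGMA_BOUNDS = (0.02, 2.0)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitSpecification:
    """What to estimate, from where to start, and optimizer settings.

    ``init`` holds natural-scale starting values (omegas and sigmas as
    log-scale SDs); parameters not listed in ``estimate`` are held fixed at
    their ``init`` value. Positive parameters are optimized on the log
    scale, fractions on the logit scale.
    """

    estimate: tuple[str, ...] = PARAM_NAMES
    init: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_INIT))
    maxiter: int = 200
    inner_maxiter: int = 60
    inner_gtol: float = 1e-4
    fd_eps: float = 1e-5
    prefit: bool = True   # naive-pooled first stage for starting values

    def __post_init__(self) -> None:
        unknown = set(self.estimate) | set(self.init) - set(PARAM_NAMES)
        unknown -= set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names {sorted(unknown)}")
        full = self.full_init()
        for name, val in full.items():
            if not np.isfinite(val):
                raise ValueError(f"initial {name}={val} is not finite")
            if name in _LOGIT_PARAMS and not 0 < val < 1:
                raise ValueError(f"initial {name}={val} must lie in (0, 1)")
            if name not in _LOGIT_PARAMS and val < 0:
                raise ValueError(f"initial {name}={val} must be nonnegative")
            # optimizer bounds apply only to parameters actually estimated
            # (a fixed omega of zero simply deactivates that random effect)
            if name in self.estimate:
                lo, hi = _natural_bounds(name)
                if not lo <= val <= hi:
                    raise ValueError(f"initial {name}={val} outside ({lo}, {hi})")

    def full_init(self) -> dict[str, float]:
        init = dict(_DEFAULT_INIT)
        init.update(self.init)
        return init


# deliberately generic round-number starting values, far from any fitted optimum
_DEFAULT_INIT = {
    "cl": 10.0, "v1_ref": 30.0, "q_ref": 30.0, "v2_ref": 30.0,
    "r_frac": 0.5, "bmax": 150.0, "kd": 30.0, "tf": 0.5,
    "rr_obese": 0.3, "rr_nonobese": 0.3,
    "omega_cl": 0.3, "omega_v1": 0.3, "omega_q": 0.3, "omega_v2": 0.3,
    "omega_bmax": 0.3, "omega_rr": 0.3, "omega_cath": 0.3,
    "sigma_plasma": 0.3, "sigma_microdialysate": 0.3,
    "sigma_retrodialysate": 0.3,
}


def _natural_bounds(name: str) -> tuple[float, float]:
    if name in _BOUNDS_NATURAL:
        return _BOUNDS_NATURAL[name]
    if name in _LOGIT_PARAMS:
        return (expit(-_LOGIT_BOUND), expit(_LOGIT_BOUND))
    if name.startswith("omega_"):
        return _OMEGA_BOUNDS
    if name.startswith("sigma_"):
        return _SIGMA_BOUNDS
    raise KeyError(name)


def _to_internal(name: str, value: float) -> float:
    return float(logit(value)) if name in _LOGIT_PARAMS else float(np.log(value))


def _from_internal(name: str, x: float) -> float:
    return float(expit(x)) if name in _LOGIT_PARAMS else float(np.exp(x))


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float              # -2 log marginal likelihood
    converged: bool
    n_iter: int
    message: str = ""
    eta_modes: dict | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, val in self.estimates.items():
            entry = {"parameter": name, "estimate": val}
            if name.startswith(("omega_", "sigma_")):
                entry["cv_pct"] = omega_to_cv(val)
            rows.append(entry)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design groups: subjects sharing one observation layout are evaluated
# together as a batch


class _DesignGroup:
    def __init__(self, subjects: list[dict], scaling: ScalingReference):
        self.scaling = scaling
        sig = subjects[0]["signature"]
        self.regimen = DosingRegimen.from_tuples(list(sig["doses"]))
        self.pt_times = np.array(sig["pt_times"])
        self.pu_times = np.array(sig["pu_times"])
        self.md = sig["md"]    # tuples (lo, hi, cath)
        self.rd = sig["rd"]    # tuples (lo, hi, cath, perf)
        self.point_times = np.concatenate([self.pt_times, self.pu_times])
        intervals = [(lo, hi) for lo, hi, *_ in self.md] + [
            (lo, hi) for lo, hi, *_ in self.rd
        ]
        self.intervals = np.array(intervals) if intervals else np.empty((0, 2))
        self.md_cath = np.array([c - 1 for *_, c in self.md], dtype=int)
        self.rd_cath = np.array([c - 1 for _, _, c, _ in self.rd], dtype=int)
        self.rd_perf = np.array([p for *_, p in self.rd])
        self.dial_cath = np.concatenate([self.md_cath, self.rd_cath]).astype(int)
        self.dial_perf = np.concatenate([np.zeros(len(self.md)), self.rd_perf])
        self.t_max = max(
            [self.point_times.max(initial=0.0)]
            + ([self.intervals.max()] if len(intervals) else [])
            + [ev.end for ev in self.regimen.events]
        )

        self.ids = [s["id"] for s in subjects]
        self.n = len(subjects)
        self.lbwr = np.array([s["lbw"] for s in subjects]) / scaling.lbw_ref
        self.fmr = np.array([s["fm"] for s in subjects]) / scaling.fm_ref
        self.obese = np.array([s["obese"] for s in subjects], dtype=bool)
        self.y_log = np.log(np.stack([s["dv"] for s in subjects]))
        n_pt, n_pu = len(self.pt_times), len(self.pu_times)
        self.stream_idx = np.array(
            [0] * (n_pt + n_pu) + [1] * len(self.md) + [2] * len(self.rd)
        )
        self.n_obs = self.y_log.shape[1]

    # -- prediction and exact data likelihood -------------------------------

    def _forward(self, theta: dict, eta: np.ndarray):
        """One forward pass: exact data -log-likelihood plus GN ingredients.

        ``eta`` has shape (..., n, 8); complex values propagate (complex-step
        differentiation), so the returned quantities are analytic in both
        ``eta`` and the entries of ``theta``.

        Every record is Gaussian on log concentration. Dialysate
        predictions use the soft-capped catheter recovery; the microdialysate
        sigma is the total per-record spread (the per-sample recovery effect
        is log-additive there and folds into it exactly).

        Returns a dict with ``nll`` (..., n) and the per-record
        log-predictions used for the Gauss-Newton Hessian.
        """
        e = lambda k: np.exp(eta[..., k])
        cl = theta["cl"] * e(0)
        v1 = theta["v1_ref"] * self.lbwr * e(1)
        q = theta["q_ref"] * self.lbwr**self.scaling.exp_q * e(2)
        r = theta["r_frac"]
        v2 = theta["v2_ref"] * (r * self.lbwr + (1.0 - r) * self.fmr) * e(3)
        bmax = theta["bmax"] * e(4)
        rr_group = np.where(self.obese, theta["rr_obese"], theta["rr_nonobese"])
        rr_sub = rr_group * e(5)

        sol = BiexponentialSolution(cl, v1, q, v2, self.regimen, self.t_max)
        cu_pts, _ = sol.concentrations(self.point_times)
        n_pt = len(self.pt_times)
        pred_pt = bind_total(cu_pts[..., :n_pt], bmax[..., None], theta["kd"])
        pred_pu = cu_pts[..., n_pt:]
        lp_plasma = np.log(
            _underflow_guard(np.concatenate([pred_pt, pred_pu], axis=-1))
        )
        n_plasma = lp_plasma.shape[-1]
        sig_pl = theta["sigma_plasma"]
        res_pl = self.y_log[:, :n_plasma] - lp_plasma
        nll = (
            0.5 * np.sum((res_pl / sig_pl) ** 2, axis=-1)
            + n_plasma * (np.log(sig_pl) + 0.5 * _LOG2PI)
        )

        lp_dial = None
        if len(self.intervals):
            _, c2bar = sol.interval_average_concentrations(self.intervals)
            isf = theta["tf"] * c2bar
            eta_cath = eta[..., 6:8]
            rr_eff = soft_cap_recovery(
                rr_sub[..., None] * np.exp(np.take(eta_cath, self.dial_cath, axis=-1))
            )
            pred_dial = _smooth_floor(
                self.dial_perf + rr_eff * (isf - self.dial_perf)
            )
            lp_dial = np.log(pred_dial)
            sig = self.dial_sigma(theta)
            res = self.y_log[:, n_plasma:] - lp_dial
            nll = nll + (
                0.5 * np.sum((res / sig) ** 2, axis=-1)
                + np.sum(np.log(sig))
                + 0.5 * res.shape[-1] * _LOG2PI
            )
        return {"nll": nll, "lp_plasma": lp_plasma, "lp_dial": lp_dial}

    def dial_sigma(self, theta) -> np.ndarray:
        """Residual log-SD per dialysate record (microdialysate then retro)."""
        return np.where(
            np.arange(len(self.md) + len(self.rd)) < len(self.md),
            theta["sigma_microdialysate"],
            theta["sigma_retrodialysate"],
        )

    # -- Laplace machinery --------------------------------------------------

    def _data_nll(self, theta, eta) -> np.ndarray:
        """Per-subject -log p(y | eta) at real-valued eta; shape (..., n)."""
        return self._forward(theta, eta)["nll"]

    def _omega_vector(self, theta) -> np.ndarray:
        return np.array(
            [theta["omega_cl"], theta["omega_v1"], theta["omega_q"],
             theta["omega_v2"], theta["omega_bmax"], theta["omega_rr"],
             theta["omega_cath"], theta["omega_cath"]]
        )

    def _grad_hess(self, theta, eta, active, prior_inv, h=1e-20):
        """Exact gradient (complex step) and Gauss-Newton Hessian."""
        d = len(active)
        pert = np.zeros((d, self.n, 8), dtype=complex)
        for j, k in enumerate(active):
            pert[j, :, k] = 1j * h
        out = self._forward(theta, eta[None, :, :] + pert)
        grad = np.moveaxis(out["nll"].imag / h, 0, -1) + eta[:, active] * prior_inv

        jac_pl = np.moveaxis(out["lp_plasma"].imag / h, 0, -1)   # (n, K_pl, d)
        hess = np.einsum("nkd,nke->nde", jac_pl, jac_pl) / theta["sigma_plasma"] ** 2

        if out["lp_dial"] is not None:
            jac_dial = np.moveaxis(out["lp_dial"].imag / h, 0, -1)  # (n, K, d)
            w = 1.0 / self.dial_sigma(theta) ** 2
            hess += np.einsum("nkd,nke,k->nde", jac_dial, jac_dial, w)
        hess[:, np.arange(d), np.arange(d)] += prior_inv
        return grad, hess

    def laplace(self, theta: dict, eta0: np.ndarray | None,
                maxiter: int = 60, gtol: float = 1e-4):
        """Laplace -log marginal likelihood for the group; returns (nll, eta)."""
        omega = self._omega_vector(theta)
        active = [k for k in range(8) if omega[k] > 1e-10]
        d = len(active)
        eta = np.zeros((self.n, 8)) if eta0 is None else eta0.copy()
        if d == 0:
            nll = float(np.sum(self._data_nll(theta, eta)))
            return nll, eta

        om_act = omega[active]
        prior_inv = 1.0 / om_act**2

        def joint(eta_full):
            pen = 0.5 * np.sum(eta_full[:, active] ** 2 * prior_inv, axis=-1)
            return self._data_nll(theta, eta_full) + pen

        f = joint(eta)
        hess = None
        f_prev_total = np.inf
        for _ in range(maxiter):
            grad, hess = self._grad_hess(theta, eta, active, prior_inv)
            gmax = np.abs(grad).max()
            if gmax < gtol:
                break
            step = -np.linalg.solve(hess, grad[..., None])[..., 0]
            norm = np.linalg.norm(step, axis=-1)
            step *= np.minimum(1.0, _MAX_ETA_STEP / np.maximum(norm, 1e-12))[:, None]
            slope = np.sum(grad * step, axis=-1)
            t = np.ones(self.n)
            eta_new = eta.copy()
            for _ in range(10):
                eta_new[:, active] = eta[:, active] + t[:, None] * step
                f_new = joint(eta_new)
                # small absolute slack tolerates round-off near the mode
                bad = f_new > f + 1e-4 * t * slope + 1e-10
                if not np.any(bad):
                    break
                t = np.where(bad, 0.5 * t, t)
            # reject any step that still increases the objective
            accept = f_new <= f + 1e-10
            eta[accept] = eta_new[accept]
            f = np.where(accept, f_new, f)
            total = float(np.sum(f))
            if not np.any(accept) or f_prev_total - total < 1e-9:
                f_prev_total = total
                break
            f_prev_total = total
        else:
            logger.debug("inner mode search hit maxiter (gmax=%.2e)", gmax)
        if gmax >= gtol:
            # refresh the Hessian at the point actually returned
            _, hess = self._grad_hess(theta, eta, active, prior_inv)

        sign, logdet = np.linalg.slogdet(hess)
        if np.any(sign <= 0):
            raise FitError("non-positive-definite Laplace Hessian")
        nll = float(np.sum(f) + np.sum(np.log(om_act)) * self.n + 0.5 * np.sum(logdet))
        return nll, eta

    def quadrature_1d(self, theta: dict, n_nodes: int = 40):
        """-log marginal likelihood by adaptive Gauss-Hermite (one active eta).

        Nodes are centered at the empirical-Bayes mode and scaled by the
        joint-objective curvature, making the rule effectively exact for a
        single random effect; used to document the Laplace approximation
        error on small cases.
        """
        omega = self._omega_vector(theta)
        active = [k for k in range(8) if omega[k] > 1e-10]
        if len(active) != 1:
            raise ValueError("quadrature integration supports exactly one active eta")
        (k,) = active
        _, eta_hat = self.laplace(theta, None)
        prior_inv = np.array([1.0 / omega[k] ** 2])
        _, hess = self._grad_hess(theta, eta_hat, active, prior_inv)
        scale = 1.0 / np.sqrt(hess[:, 0, 0])            # (n,)
        x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
        eta_nodes = np.zeros((n_nodes, self.n, 8))
        eta_nodes[..., k] = eta_hat[:, k] + scale * x[:, None]
        ll = -self._data_nll(theta, eta_nodes)          # (n_nodes, n)
        log_g = (
            ll
            - 0.5 * (eta_nodes[..., k] / omega[k]) ** 2
            - np.log(omega[k] * np.sqrt(2 * np.pi))
            + 0.5 * x[:, None] ** 2
        )
        m = log_g.max(axis=0)
        lme = (
            np.log(scale)
            + 0.5 * np.log(2 * np.pi)
            + m
            + np.log(np.sum((w / np.sqrt(2 * np.pi))[:, None] * np.exp(log_g - m), axis=0))
        )
        return float(-np.sum(lme))

    def monte_carlo(self, theta: dict, rng: np.random.Generator, n_draws: int = 500):
        """-log marginal likelihood by plain Monte Carlo over the prior."""
        omega = self._omega_vector(theta)
        chunk = max(1, int(2e6 / (self.n * max(self.n_obs, 1))))
        lls = []
        done = 0
        while done < n_draws:
            k = min(chunk, n_draws - done)
            draws = rng.normal(size=(k, self.n, 8)) * omega
            lls.append(-self._data_nll(theta, draws))   # (k, n)
            done += k
        ll = np.concatenate(lls, axis=0)
        m = ll.max(axis=0)
        lme = m + np.log(np.mean(np.exp(ll - m), axis=0))
        return float(-np.sum(lme))


def _subject_record(sid, sub: pd.DataFrame) -> dict:
    doses = tuple(subject_regimen_events(sub))
    obs = sub[sub["EVID"] == 0]
    pt = obs[obs["DVID"] == 1].sort_values("TIME")
    pu = obs[obs["DVID"] == 2].sort_values("TIME")
    md = obs[obs["DVID"] == 3].sort_values(["CATH", "ISTART"])
    rd = obs[obs["DVID"] == 4].sort_values(["CATH", "ISTART"])
    sig = {
        "doses": doses,
        "pt_times": tuple(pt["TIME"]),
        "pu_times": tuple(pu["TIME"]),
        "md": tuple(zip(md["ISTART"], md["IEND"], md["CATH"].astype(int))),
        "rd": tuple(zip(rd["ISTART"], rd["IEND"], rd["CATH"].astype(int), rd["PERF"])),
    }
    dv = np.concatenate([pt["DV"], pu["DV"], md["DV"], rd["DV"]])
    if np.any(dv <= 0):
        raise FitError(f"subject {sid}: nonpositive DV cannot enter the log-normal model")
    first = sub.iloc[0]
    return {
        "id": sid,
        "signature": sig,
        "dv": dv,
        "lbw": float(first["LBW"]),
        "fm": float(first["FM"]),
        "obese": bool(first["OBESE"]),
    }


def build_groups(
    dataset: pd.DataFrame, scaling: ScalingReference | None = None
) -> list[_DesignGroup]:
    """Group subjects by identical observation design for batched evaluation."""
    validate_dataset(dataset)
    scaling = scaling or ScalingReference()
    recs = [_subject_record(sid, sub) for sid, sub in dataset.groupby("ID", sort=False)]
    keyed: dict = {}
    for rec in recs:
        key = (
            rec["signature"]["doses"], rec["signature"]["pt_times"],
            rec["signature"]["pu_times"], rec["signature"]["md"],
            rec["signature"]["rd"],
        )
        keyed.setdefault(key, []).append(rec)
    return [_DesignGroup(subs, scaling) for subs in keyed.values()]


def theta_from_population(pop) -> dict:
    """Natural-scale parameter dict of :data:`PARAM_NAMES` from population defaults."""
    from .simulate import cv_to_omega

    om = {k: cv_to_omega(v) for k, v in pop.omega_cv.items()}
    return {
        "cl": pop.cl, "v1_ref": pop.v1_ref, "q_ref": pop.q_ref,
        "v2_ref": pop.v2_ref, "r_frac": pop.r_frac, "bmax": pop.bmax,
        "kd": pop.kd, "tf": pop.tf, "rr_obese": pop.rr_obese,
        "rr_nonobese": pop.rr_nonobese,
        "omega_cl": om["cl"], "omega_v1": om["v1"], "omega_q": om["q"],
        "omega_v2": om["v2"], "omega_bmax": om["bmax"], "omega_rr": om["rr"],
        "omega_cath": cv_to_omega(pop.catheter_cv["intercatheter"]),
        # the per-sample (intracatheter) recovery effect is log-additive on
        # microdialysate records and folds exactly into their residual SD
        "sigma_microdialysate": float(np.sqrt(
            cv_to_omega(pop.sigma_cv["microdialysate"]) ** 2
            + cv_to_omega(pop.catheter_cv["intracatheter"]) ** 2
        )),
        "sigma_plasma": cv_to_omega(pop.sigma_cv["plasma"]),
        "sigma_retrodialysate": cv_to_omega(pop.sigma_cv["retrodialysate"]),
    }


# ---------------------------------------------------------------------------
# public likelihood surface


def individual_loglik(params: dict, subject: pd.DataFrame, sigmas: dict) -> float:
    """Reference log-likelihood of one subject's records at fixed parameters.

    ``params`` holds cl, v1, q, v2, bmax, kd, tf and the per-catheter
    recoveries rr_cath (mapping catheter number -> RR, soft-capped below 1
    like the fitted model); ``sigmas`` the per-stream log-scale residual SDs
    (for microdialysate: the total per-record spread). Predictions are built
    through the plain (non-batched) kinetics API, including trapezoidal
    dialysate integration, so this path is an independent check of the
    vectorized likelihood used for fitting.
    """
    from .kinetics import dialysate_concentration, solve_unbound
    from .params import IndividualParameters

    obs = subject[subject["EVID"] == 0]
    if obs.empty:
        return 0.0
    ind = IndividualParameters(
        cl=params["cl"], v1=params["v1"], q=params["q"], v2=params["v2"],
        bmax=params["bmax"], kd=params["kd"], tf=params["tf"],
    )
    regimen = DosingRegimen.from_tuples(subject_regimen_events(subject))
    t_max = max(
        float(obs["TIME"].max()),
        float(np.nanmax(obs["IEND"].values)) if obs["IEND"].notna().any() else 0.0,
    )
    grid = np.linspace(0.0, t_max, max(int(t_max / 0.005), 10) + 1)
    profile = solve_unbound(ind, regimen, grid)

    def gauss(y, pred, sigma):
        z = (np.log(y) - np.log(pred)) / sigma
        return -0.5 * z**2 - np.log(sigma) - 0.5 * _LOG2PI

    total = 0.0
    for _, row in obs.iterrows():
        dvid = int(row["DVID"])
        if dvid == 1:
            cu = np.interp(row["TIME"], grid, profile.cu_plasma)
            total += gauss(row["DV"], float(bind_total(cu, ind.bmax, ind.kd)),
                           sigmas["plasma"])
        elif dvid == 2:
            pred = float(np.interp(row["TIME"], grid, profile.cu_plasma))
            total += gauss(row["DV"], pred, sigmas["plasma"])
        else:
            rr = soft_cap_recovery(params["rr_cath"][int(row["CATH"])])
            perf = 0.0 if dvid == 3 else float(row["PERF"])
            mean_isf = dialysate_concentration(
                profile, (row["ISTART"], row["IEND"]), rr=1.0, perfusate=0.0
            )
            pred = _smooth_floor(perf + rr * (mean_isf - perf))
            sigma = sigmas["microdialysate" if dvid == 3 else "retrodialysate"]
            total += gauss(row["DV"], pred, sigma)
    return float(total)


def marginal_loglik(
    theta: dict,
    dataset: pd.DataFrame,
    method: str = "laplace",
    rng: np.random.Generator | None = None,
    n_draws: int = 500,
    scaling: ScalingReference | None = None,
) -> float:
    """Log marginal likelihood of the dataset at natural-scale parameters.

    ``theta`` uses the :data:`PARAM_NAMES` keys. ``method`` is "laplace"
    (default) or "mc" (plain Monte Carlo over the random-effect prior, for
    verification on small problems).
    """
    groups = build_groups(dataset, scaling)
    total = 0.0
    for g in groups:
        if method == "laplace":
            nll, _ = g.laplace(theta, None)
        elif method == "mc":
            nll = g.monte_carlo(theta, rng or np.random.default_rng(0), n_draws)
        elif method == "quadrature":
            nll = g.quadrature_1d(theta)
        else:
            raise ValueError(f"unknown method {method!r}")
        total += nll
    return -total


def _run_stage(groups, est, init, spec, warm, maxiter):
    """One L-BFGS-B pass over the named parameters; returns (result, theta)."""
    x0 = np.array([_to_internal(name, init[name]) for name in est])
    bounds = [
        tuple(_to_internal(name, b) for b in _natural_bounds(name)) for name in est
    ]

    def theta_of(x) -> dict:
        theta = dict(init)
        for name, xi in zip(est, x):
            theta[name] = _from_internal(name, xi)
        return theta

    def objective(x) -> float:
        theta = theta_of(x)
        total = 0.0
        for i, g in enumerate(groups):
            nll, eta = g.laplace(
                theta, warm[i], maxiter=spec.inner_maxiter, gtol=spec.inner_gtol
            )
            warm[i] = eta
            total += nll
        return total

    f0 = objective(x0)
    if not np.isfinite(f0):
        raise FitError(f"objective not finite at initial values ({f0})")
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": maxiter,
            "eps": spec.fd_eps,
            "ftol": 1e-10,
            "gtol": 1e-5,
        },
    )
    return res, theta_of(res.x)


def fit(dataset: pd.DataFrame, spec: FitSpecification | None = None) -> FitResult:
    """Maximize the Laplace marginal likelihood over the requested parameters.

    Two stages: a naive-pooled prefit (all random effects switched off, so no
    inner mode search) moves the fixed effects and residual magnitudes from
    their generic starting values into the right region cheaply; the full
    hierarchical fit then starts near its optimum.
    """
    spec = spec or FitSpecification()
    groups = build_groups(dataset)
    init = spec.full_init()
    est = list(spec.estimate)
    warm: dict[int, np.ndarray | None] = {i: None for i in range(len(groups))}

    pooled_names = [n for n in est if not n.startswith("omega_")]
    has_etas = any(init.get(n, 0.0) > 1e-10 for n in PARAM_NAMES
                   if n.startswith("omega_"))
    if spec.prefit and pooled_names and has_etas:
        pooled_init = dict(init)
        for name in PARAM_NAMES:
            if name.startswith("omega_"):
                pooled_init[name] = 0.0
        pooled_warm = {i: None for i in range(len(groups))}
        _, pooled_theta = _run_stage(
            groups, pooled_names, pooled_init, spec, pooled_warm, maxiter=120
        )
        init = dict(init)
        for name in pooled_names:
            init[name] = pooled_theta[name]

    res, theta = _run_stage(groups, est, init, spec, warm, maxiter=spec.maxiter)
    estimates = {name: theta[name] for name in PARAM_NAMES}
    eta_modes = {
        tuple(g.ids): warm[i] for i, g in enumerate(groups) if warm[i] is not None
    }
    return FitResult(
        estimates=estimates,
        objective=2.0 * float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        eta_modes=eta_modes,
    )
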