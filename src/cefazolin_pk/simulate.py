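"""Monte Carlo population simulation of unbound cefazolin profiles.

Individual structural parameters are the covariate-scaled typical values
multiplied by independent log-normal interindividual random effects
(log-scale SD ``omega = sqrt(ln(1 + CV^2))``, so the stated CV is exact).
The dissociation constant carries no variability. Residual (assay) error is
deliberately excluded here: target-attainment metrics are computed on true
concentration profiles, not noisy measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariates import PatientCovariates, apply_covariate_model
from .kinetics import BiexponentialSolution, DosingRegimen, SimulatedProfile
from .params import IndividualParameters, PopulationParameters


class ModelGridError(ValueError):
    """Raised when the regimen does not fit inside the simulation grid."""


def cv_to_omega(cv_pct: float) -> float:
    """Log-scale SD of a log-normal with the given coefficient of variation (%)."""
    if cv_pct < 0:
        raise ValueError("CV must be nonnegative")
    return float(np.sqrt(np.log1p((cv_pct / 100.0) ** 2)))


def omega_to_cv(omega: float) -> float:
    """Inverse of :func:`cv_to_omega`, in percent."""
    return float(np.sqrt(np.expm1(omega**2)) * 100.0)


@dataclass(frozen=True)
class ReferencePatient:
    """A simulation reference patient defined by TBW and fat-mass percentage."""

    label: str
    tbw: float      # kg
    fm_pct: float   # % of TBW
    bmi: float      # kg/m^2, descriptive only

    @property
    def fm(self) -> float:
        return self.tbw * self.fm_pct / 100.0

    @property
    def lbw(self) -> float:
        return self.tbw - self.fm

    def covariates(self) -> PatientCovariates:
        return PatientCovariates(
            subject_id=self.label,
            sex="female",
            age=45.0,
            tbw=self.tbw,
            obese=self.label != "nonobese",
            lbw=self.lbw,
            fm=self.fm,
            bmi=self.bmi,
        )


REFERENCE_PATIENTS: dict[str, ReferencePatient] = {
    "nonobese": ReferencePatient("nonobese", tbw=70.0, fm_pct=24.8, bmi=24.2),
    "obese": ReferencePatient("obese", tbw=95.1, fm_pct=29.5, bmi=33.0),
    "morbidly_obese": ReferencePatient("morbidly_obese", tbw=127.0, fm_pct=39.5, bmi=44.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 1000
    seed: int = 0
    t_end: float = 8.0
    dt: float = 0.01           # h; grid step for trajectory evaluation
    include_residual_error: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt))
        return np.linspace(0.0, self.t_end, n + 1)


_IIV_PARAMS = ("cl", "v1", "q", "v2", "bmax")  # kd carries no variability


def _draw_etas(pop: PopulationParameters, n: int, rng: np.random.Generator) -> dict:
    etas = {}
    for name in _IIV_PARAMS:
        omega = cv_to_omega(pop.omega_cv.get(name, 0.0))
        etas[name] = rng.normal(0.0, omega, size=n) if omega > 0 else np.zeros(n)
    return etas


def draw_individual(
    pop: PopulationParameters, cov: PatientCovariates, rng: np.random.Generator
) -> IndividualParameters:
    """One individual: covariate scaling first, then log-normal variability."""
    typ = apply_covariate_model(pop, cov)
    etas = _draw_etas(pop, 1, rng)
    return IndividualParameters(
        cl=typ.cl * float(np.exp(etas["cl"][0])),
        v1=typ.v1 * float(np.exp(etas["v1"][0])),
        q=typ.q * float(np.exp(etas["q"][0])),
        v2=typ.v2 * float(np.exp(etas["v2"][0])),
        bmax=typ.bmax * float(np.exp(etas["bmax"][0])),
        kd=typ.kd,
        tf=typ.tf,
    )


@dataclass
class ProfileEnsemble:
    """Simulated profiles of a virtual population on a shared time grid.

    Trajectories are stored as (n_subjects, n_times) arrays; iterating yields
    per-subject :class:`SimulatedProfile` objects.
    """

    times: np.ndarray
    cu_plasma: np.ndarray
    c2: np.ndarray
    tf: float
    bmax: float = field(default=247.0)
    kd: float = field(default=65.3)

    @property
    def n_subjects(self) -> int:
        return self.cu_plasma.shape[0]

    @property
    def c_isf(self) -> np.ndarray:
        return self.tf * self.c2

    def trajectory(self, matrix: str) -> np.ndarray:
        if matrix == "plasma_unbound":
            return self.cu_plasma
        if matrix == "isf":
            return self.c_isf
        raise ValueError(f"unknown matrix {matrix!r} (use 'plasma_unbound' or 'isf')")

    def subject(self, i: int) -> SimulatedProfile:
        return SimulatedProfile.from_states(
            self.times, self.cu_plasma[i], self.c2[i], self.tf, self.bmax, self.kd
        )

    def __iter__(self):
        return (self.subject(i) for i in range(self.n_subjects))

    def median_profile(self, matrix: str = "plasma_unbound") -> np.ndarray:
        return np.median(self.trajectory(matrix), axis=0)


def simulate_population(
    pop: PopulationParameters,
    patient: ReferencePatient | PatientCovariates,
    regimen: DosingRegimen,
    config: SimulationConfig,
) -> ProfileEnsemble:
    """Simulate ``config.n_subjects`` independent individuals for one regimen."""
    cov = patient.covariates() if isinstance(patient, ReferencePatient) else patient
    typ = apply_covariate_model(pop, cov)
    times = config.time_grid()
    last_end = max(ev.end for ev in regimen.events)
    if last_end > times[-1]:
        raise ModelGridError(
            f"regimen extends to {last_end} h beyond the {times[-1]} h grid"
        )
    rng = np.random.default_rng(config.seed)
    etas = _draw_etas(pop, config.n_subjects, rng)
    sol = BiexponentialSolution(
        typ.cl * np.exp(etas["cl"]),
        typ.v1 * np.exp(etas["v1"]),
        typ.q * np.exp(etas["q"]),
        typ.v2 * np.exp(etas["v2"]),
        regimen,
        t_max=float(times[-1]),
    )
    cu, c2 = sol.concentrations(times)
    return ProfileEnsemble(
        times=times, cu_plasma=cu, c2=c2, tf=typ.tf, bmax=typ.bmax, kd=typ.kd
    )


def export_profiles(ensemble: ProfileEnsemble, path, thin: int = 1) -> None:
    """Write profiles as long-format delimited text (subject, time, cu, c_isf)."""
    import pandas as pd

    t = ensemble.times[::thin]
    frames = []
    for i in range(ensemble.n_subjects):
        frames.append(
            pd.DataFrame(
                {
                    "subject": i,
                    "time": t,
                    "cu_plasma": ensemble.cu_plasma[i, ::thin],
                    "c_isf": ensemble.c_isf[i, ::thin],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
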