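"""Population parameters of the final unbound-cefazolin model.

The model is a two-compartment disposition model for unbound cefazolin with
linear elimination, a saturable (single-site, Langmuir-type) plasma protein
binding map between unbound and total central concentrations, and a
microdialysis observation layer: interstitial-space-fluid (ISF) concentration
is a tissue scaling factor ``tf`` times the peripheral-compartment
concentration, and dialysate concentrations are relative-recovery-weighted
time averages of ISF concentration over each collection interval.

Defaults are the published population estimates for obese and nonobese
surgical patients (central volume and intercompartmental flow scaled on lean
body weight, peripheral volume on a lean-body-weight / fat-mass mixture).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ScalingReference:
    """Reference body-size descriptors and allometric exponents.

    ``v1`` scales as (LBW/lbw_ref)**exp_v1, ``q`` as (LBW/lbw_ref)**exp_q and
    ``v2`` as a convex combination ``r_frac*LBW/lbw_ref + (1-r_frac)*FM/fm_ref``
    (the ``r_frac`` lives on :class:`PopulationParameters`).
    """

    lbw_ref: float = 64.3   # kg
    fm_ref: float = 41.5    # kg
    exp_v1: float = 1.0
    exp_q: float = 0.75


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, variability and residual-error magnitudes.

    Units: clearances L/h, volumes L, binding parameters mg/L, fractions
    dimensionless in (0, 1]; all variability magnitudes are coefficients of
    variation in percent under a log-normal convention.
    """

    cl: float = 17.9          # L/h, unbound clearance (no covariates)
    v1_ref: float = 22.9      # L at LBW = lbw_ref
    q_ref: float = 56.8       # L/h at LBW = lbw_ref
    v2_ref: float = 34.3      # L at LBW = lbw_ref, FM = fm_ref
    r_frac: float = 0.764     # share of V2 scaled with LBW (rest with FM)
    bmax: float = 247.0       # mg/L, maximum plasma binding capacity
    kd: float = 65.3          # mg/L, binding dissociation constant
    tf: float = 0.655         # ISF = tf * peripheral concentration
    rr_obese: float = 0.233   # microdialysis relative recovery, obese
    rr_nonobese: float = 0.411

    # interindividual variability, CV%
    omega_cv: dict[str, float] = field(
        default_factory=lambda: {
            "cl": 21.9,
            "v1": 40.1,
            "q": 54.8,
            "v2": 12.4,
            "bmax": 9.20,
            "rr": 43.3,
        }
    )
    # catheter-level variability on relative recovery, CV%
    catheter_cv: dict[str, float] = field(
        default_factory=lambda: {"intercatheter": 58.6, "intracatheter": 90.3}
    )
    # proportional residual error per observation stream, CV%
    sigma_cv: dict[str, float] = field(
        default_factory=lambda: {
            "plasma": 35.7,
            "microdialysate": 52.1,
            "retrodialysate": 28.9,
        }
    )

    scaling: ScalingReference = field(default_factory=ScalingReference)

    def __post_init__(self) -> None:
        for name in ("cl", "v1_ref", "q_ref", "v2_ref", "bmax", "kd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("r_frac", "tf", "rr_obese", "rr_nonobese"):
            val = getattr(self, name)
            if not 0 < val <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for mapping in (self.omega_cv, self.catheter_cv, self.sigma_cv):
            for key, val in mapping.items():
                if val < 0:
                    raise ValueError(f"negative CV for {key!r}")

    def without_variability(self) -> "PopulationParameters":
        """Copy with all interindividual / catheter CVs set to zero."""
        return replace(
            self,
            omega_cv={k: 0.0 for k in self.omega_cv},
            catheter_cv={k: 0.0 for k in self.catheter_cv},
        )

    def rr_for_group(self, obese: bool) -> float:
        return self.rr_obese if obese else self.rr_nonobese


@dataclass(frozen=True)
class IndividualParameters:
    """Structural parameters of one (real or simulated) individual."""

    cl: float
    v1: float
    q: float
    v2: float
    bmax: float = 247.0
    kd: float = 65.3
    tf: float = 0.655

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2", "bmax", "kd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
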