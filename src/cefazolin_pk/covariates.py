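"""Body-size descriptors and the covariate model.

Raw covariates (sex, age, total body weight, height) are expanded into the
derived descriptors used in obesity pharmacokinetics: lean body weight (LBW,
Janmahasatian), ideal body weight (IBW, Devine), adjusted body weight
(ABW = IBW + 0.4*(TBW - IBW)), fat mass (FM = TBW - LBW) and BMI.

The final covariate model scales central volume linearly with LBW,
intercompartmental flow with LBW**0.75, and peripheral volume with a convex
LBW/FM combination; clearance carries no covariate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .params import IndividualParameters, PopulationParameters, ScalingReference

logger = logging.getLogger(__name__)

_CM_PER_INCH = 2.54


class InvalidCovariateError(ValueError):
    """Raised for physiologically impossible or missing covariates."""


def compute_lbw(sex: str, tbw: float, bmi: float) -> float:
    """Lean body weight (kg) by the Janmahasatian formula.

    LBW = 9270*TBW / (6680 + 216*BMI) for males and
    9270*TBW / (8780 + 244*BMI) for females.
    """
    if tbw <= 0 or bmi <= 0:
        raise InvalidCovariateError(f"tbw and bmi must be positive, got {tbw}, {bmi}")
    if sex == "male":
        return 9270.0 * tbw / (6680.0 + 216.0 * bmi)
    if sex == "female":
        return 9270.0 * tbw / (8780.0 + 244.0 * bmi)
    raise InvalidCovariateError(f"unknown sex {sex!r}")


def compute_ibw(sex: str, height: float) -> float:
    """Ideal body weight (kg) by the Devine formula; ``height`` in cm.

    Heights below 60 inches are floored at the sex-specific base value
    (50 kg male / 45.5 kg female) rather than extrapolated downwards.
    """
    if height <= 0:
        raise InvalidCovariateError(f"height must be positive, got {height}")
    base = {"male": 50.0, "female": 45.5}.get(sex)
    if base is None:
        raise InvalidCovariateError(f"unknown sex {sex!r}")
    inches_over = height / _CM_PER_INCH - 60.0
    if inches_over < 0:
        logger.warning(
            "height %.1f cm below 60 in; ideal body weight floored at %.1f kg",
            height, base,
        )
        return base
    return base + 2.3 * inches_over


def compute_abw(ibw: float, tbw: float) -> float:
    """Adjusted body weight (kg): IBW + 0.4*(TBW - IBW)."""
    if ibw <= 0 or tbw <= 0:
        raise InvalidCovariateError("ibw and tbw must be positive")
    return ibw + 0.4 * (tbw - ibw)


@dataclass(frozen=True)
class PatientCovariates:
    """Raw and derived covariates of one subject.

    ``lbw``/``fm``/``bmi`` may be supplied directly (reference patients are
    defined by TBW and a fat-mass percentage, without a height); otherwise
    they are derived from sex, TBW and height via :func:`derive_covariates`.
    eGFR is carried but has no effect in the final model.
    """

    subject_id: str
    sex: str
    age: float
    tbw: float
    height: float | None = None
    obese: bool = False
    lbw: float | None = None
    fm: float | None = None
    bmi: float | None = None
    ibw: float | None = None
    abw: float | None = None
    egfr: float | None = None

    def __post_init__(self) -> None:
        if self.tbw <= 0:
            raise InvalidCovariateError("tbw must be positive")
        if self.lbw is not None and not 0 < self.lbw < self.tbw:
            raise InvalidCovariateError("lbw must satisfy 0 < lbw < tbw")
        if self.fm is not None and self.fm < 0:
            raise InvalidCovariateError("fm must be nonnegative")
        if self.bmi is not None and self.bmi <= 0:
            raise InvalidCovariateError("bmi must be positive")


def derive_covariates(cov: PatientCovariates) -> PatientCovariates:
    """Fill missing derived descriptors (BMI, LBW, FM, IBW, ABW).

    BMI requires height when absent; LBW then follows from the Janmahasatian
    formula and FM as TBW - LBW.
    """
    bmi = cov.bmi
    if bmi is None:
        if cov.height is None:
            raise InvalidCovariateError(
                f"subject {cov.subject_id}: need height (or explicit bmi)"
            )
        bmi = cov.tbw / (cov.height / 100.0) ** 2
    lbw = cov.lbw if cov.lbw is not None else compute_lbw(cov.sex, cov.tbw, bmi)
    fm = cov.fm if cov.fm is not None else cov.tbw - lbw
    ibw = cov.ibw
    abw = cov.abw
    if ibw is None and cov.height is not None:
        ibw = compute_ibw(cov.sex, cov.height)
    if abw is None and ibw is not None:
        abw = compute_abw(ibw, cov.tbw)
    return replace(cov, bmi=bmi, lbw=lbw, fm=fm, ibw=ibw, abw=abw)


def apply_covariate_model(
    pop: PopulationParameters,
    cov: PatientCovariates,
    ref: ScalingReference | None = None,
) -> IndividualParameters:
    """Typical structural parameters of a subject with given body composition.

    CL is covariate-free; V1 = v1_ref*(LBW/lbw_ref)**exp_v1;
    Q = q_ref*(LBW/lbw_ref)**exp_q;
    V2 = v2_ref*(r_frac*LBW/lbw_ref + (1 - r_frac)*FM/fm_ref).
    """
    if ref is None:
        ref = pop.scaling
    if cov.lbw is None or cov.fm is None:
        raise InvalidCovariateError(
            f"subject {cov.subject_id}: lbw/fm missing; call derive_covariates first"
        )
    lbw_frac = cov.lbw / ref.lbw_ref
    fm_frac = cov.fm / ref.fm_ref
    return IndividualParameters(
        cl=pop.cl,
        v1=pop.v1_ref * lbw_frac**ref.exp_v1,
        q=pop.q_ref * lbw_frac**ref.exp_q,
        v2=pop.v2_ref * (pop.r_frac * lbw_frac + (1.0 - pop.r_frac) * fm_frac),
        bmax=pop.bmax,
        kd=pop.kd,
        tf=pop.tf,
    )


# ---------------------------------------------------------------------------
# covariate table I/O

_REQUIRED_COLUMNS = ("subject_id", "sex", "age", "tbw")


def covariates_to_frame(cohort: Iterable[PatientCovariates]) -> pd.DataFrame:
    rows = []
    for cov in cohort:
        rows.append(
            {
                "subject_id": cov.subject_id,
                "sex": cov.sex,
                "age": cov.age,
                "tbw": cov.tbw,
                "height": cov.height if cov.height is not None else math.nan,
                "obese": int(cov.obese),
                "lbw": cov.lbw if cov.lbw is not None else math.nan,
                "fm": cov.fm if cov.fm is not None else math.nan,
                "bmi": cov.bmi if cov.bmi is not None else math.nan,
                "ibw": cov.ibw if cov.ibw is not None else math.nan,
                "abw": cov.abw if cov.abw is not None else math.nan,
                "egfr": cov.egfr if cov.egfr is not None else math.nan,
            }
        )
    return pd.DataFrame(rows)


def read_covariate_table(path, sep: str = ",") -> list[PatientCovariates]:
    """Read a delimited covariate table, deriving missing descriptor columns."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidCovariateError(f"covariate table lacks columns {missing}")

    def _get(row, name):
        if name in row.index and pd.notna(row[name]):
            return float(row[name])
        return None

    cohort = []
    for _, row in df.iterrows():
        cov = PatientCovariates(
            subject_id=str(row["subject_id"]),
            sex=str(row["sex"]),
            age=float(row["age"]),
            tbw=float(row["tbw"]),
            height=_get(row, "height"),
            obese=bool(row["obese"]) if "obese" in df.columns else False,
            lbw=_get(row, "lbw"),
            fm=_get(row, "fm"),
            bmi=_get(row, "bmi"),
            ibw=_get(row, "ibw"),
            abw=_get(row, "abw"),
            egfr=_get(row, "egfr"),
        )
        cohort.append(derive_covariates(cov))
    return cohort
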