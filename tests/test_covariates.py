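"""Body-size descriptors and the covariate model."""

import numpy as np
import pytest

from cefazolin_pk import (
    PatientCovariates,
    PopulationParameters,
    apply_covariate_model,
    compute_abw,
    compute_ibw,
    compute_lbw,
    derive_covariates,
)
from cefazolin_pk.covariates import (
    InvalidCovariateError,
    covariates_to_frame,
    read_covariate_table,
)


@pytest.mark.parametrize(
    "sex, tbw, bmi, expected",
    [
        ("male", 80.0, 26.1, 60.21),     # Janmahasatian, direct evaluation
        ("female", 70.0, 24.2, 44.19),
    ],
)
def test_lean_body_weight(sex, tbw, bmi, expected):
    assert compute_lbw(sex, tbw, bmi) == pytest.approx(expected, abs=0.01)


def test_lbw_proportional_in_tbw():
    small = compute_lbw("male", 1e-6, 25.0)
    assert small == pytest.approx(1e-6 * compute_lbw("male", 1.0, 25.0))


@pytest.mark.parametrize("sex,tbw,bmi", [("male", -1, 25), ("female", 70, 0)])
def test_lbw_invalid_inputs(sex, tbw, bmi):
    with pytest.raises(InvalidCovariateError):
        compute_lbw(sex, tbw, bmi)


@pytest.mark.parametrize(
    "sex, height, expected",
    [
        ("male", 177.8, 73.0),    # 70 in
        ("female", 152.4, 45.5),  # exactly 60 in
        ("male", 152.4, 50.0),
        ("male", 140.0, 50.0),    # below 60 in floors at the base value
    ],
)
def test_ideal_body_weight(sex, height, expected):
    assert compute_ibw(sex, height) == pytest.approx(expected, abs=0.05)


@pytest.mark.parametrize(
    "ibw, tbw, expected",
    [(60.0, 160.0, 100.0), (60.0, 60.0, 60.0), (59.4, 78.0, 66.84)],
)
def test_adjusted_body_weight(ibw, tbw, expected):
    assert compute_abw(ibw, tbw) == pytest.approx(expected, abs=0.01)


def _cov(lbw, fm):
    return PatientCovariates(
        subject_id="x", sex="female", age=45, tbw=lbw + fm, lbw=lbw, fm=fm, bmi=30
    )


class TestCovariateModel:
    def test_reference_covariates_reproduce_typical_values(self, pop):
        ind = apply_covariate_model(pop, _cov(64.3, 41.5))
        assert ind.cl == pytest.approx(17.9, abs=1e-12)
        assert ind.v1 == pytest.approx(22.9, abs=1e-12)
        assert ind.q == pytest.approx(56.8, abs=1e-12)
        assert ind.v2 == pytest.approx(34.3, abs=1e-12)

    def test_v2_without_fat_mass(self, pop):
        # fat-mass term vanishes: V2 = 34.3 * 0.764
        ind = apply_covariate_model(pop, _cov(64.3, 1e-12))
        assert ind.v2 == pytest.approx(34.3 * 0.764, rel=1e-9)

    def test_nonobese_reference_patient_v2(self, pop):
        # TBW 70 kg at 24.8% fat mass
        ind = apply_covariate_model(pop, _cov(52.64, 17.36))
        assert ind.v2 == pytest.approx(24.84, abs=0.01)

    def test_clearance_carries_no_covariate(self, pop):
        for lbw, fm in [(40, 10), (64.3, 41.5), (90, 100)]:
            assert apply_covariate_model(pop, _cov(lbw, fm)).cl == pop.cl

    def test_monotone_in_body_size(self, pop):
        lbws = np.linspace(35, 95, 13)
        fms = np.linspace(10, 120, 13)
        v1 = [apply_covariate_model(pop, _cov(l, 20)).v1 for l in lbws]
        q = [apply_covariate_model(pop, _cov(l, 20)).q for l in lbws]
        v2_l = [apply_covariate_model(pop, _cov(l, 20)).v2 for l in lbws]
        v2_f = [apply_covariate_model(pop, _cov(60, f)).v2 for f in fms]
        for seq in (v1, q, v2_l, v2_f):
            assert np.all(np.diff(seq) > 0)

    def test_missing_lbw_fm_rejected(self, pop):
        cov = PatientCovariates(subject_id="x", sex="male", age=40, tbw=80)
        with pytest.raises(InvalidCovariateError):
            apply_covariate_model(pop, cov)


def test_derive_covariates_consistency():
    cov = derive_covariates(
        PatientCovariates(
            subject_id="s", sex="female", age=50, tbw=90.0, height=165.0
        )
    )
    assert cov.bmi == pytest.approx(90.0 / 1.65**2)
    assert cov.lbw == pytest.approx(compute_lbw("female", 90.0, cov.bmi))
    assert cov.lbw + cov.fm == pytest.approx(cov.tbw)
    assert cov.ibw == pytest.approx(compute_ibw("female", 165.0))
    assert cov.abw == pytest.approx(compute_abw(cov.ibw, 90.0))


def test_covariate_table_roundtrip(tmp_path, study):
    cohort, _ = study
    path = tmp_path / "cov.csv"
    covariates_to_frame(cohort).to_csv(path, index=False)
    back = read_covariate_table(path)
    assert len(back) == len(cohort.subjects)
    for a, b in zip(cohort, back):
        assert a.subject_id == b.subject_id
        assert a.lbw == pytest.approx(b.lbw)
        assert a.obese == b.obese


def test_covariate_table_fills_derived_columns(tmp_path):
    path = tmp_path / "cov.csv"
    path.write_text(
        "subject_id,sex,age,tbw,height,obese\nA,male,44,82,178,0\n"
    )
    (cov,) = read_covariate_table(path)
    assert cov.bmi == pytest.approx(82 / 1.78**2)
    assert 0 < cov.lbw < cov.tbw
    assert cov.fm == pytest.approx(cov.tbw - cov.lbw)
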