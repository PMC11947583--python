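"""Virtual trial generation and the event-record dataset format."""

import numpy as np
import pandas as pd
import pytest

from cefazolin_pk import PopulationParameters, StudyDesign, generate_cohort
from cefazolin_pk.covariates import apply_covariate_model
from cefazolin_pk.dataset import (
    DatasetError,
    read_dataset,
    validate_dataset,
    write_dataset,
)
from cefazolin_pk.study import generate_observations, generate_study, soft_cap_recovery


class TestCohort:
    def test_counts_and_sex_ratio(self, study):
        cohort, _ = study
        df = pd.DataFrame(
            {"obese": [c.obese for c in cohort], "sex": [c.sex for c in cohort]}
        )
        assert len(cohort) == 30
        assert df["obese"].sum() == 15
        assert (df["sex"] == "male").sum() == 10

    def test_bmi_windows(self, study):
        cohort, _ = study
        for c in cohort:
            if c.obese:
                assert 39.5 <= c.bmi <= 69.3
            else:
                assert 18.7 <= c.bmi <= 29.8

    def test_body_composition_consistency(self, study):
        cohort, _ = study
        for c in cohort:
            assert c.lbw + c.fm == pytest.approx(c.tbw)
            assert 0 < c.lbw < c.tbw

    def test_group_weight_medians_near_trial(self):
        cohort = generate_cohort(StudyDesign(n_obese=200, n_nonobese=200), seed=5)
        tbw = pd.DataFrame(
            {"tbw": [c.tbw for c in cohort], "obese": [c.obese for c in cohort]}
        )
        med = tbw.groupby("obese")["tbw"].median()
        assert med[False] == pytest.approx(78.0, rel=0.15)
        assert med[True] == pytest.approx(155.0, rel=0.15)

    def test_seed_reproducibility(self):
        a = generate_cohort(StudyDesign(), seed=77)
        b = generate_cohort(StudyDesign(), seed=77)
        assert [c.tbw for c in a] == [c.tbw for c in b]


class TestObservations:
    def test_record_counts_per_subject(self, study):
        _, df = study
        obs = df[df["EVID"] == 0]
        counts = obs.groupby(["ID", "DVID"]).size().unstack()
        assert (counts[1] == 8).all()    # plasma total
        assert (counts[2] == 4).all()    # plasma unbound (ultrafiltration)
        assert (counts[3] == 20).all()   # microdialysate, 10 intervals x 2 catheters
        assert (counts[4] == 6).all()    # retrodialysate, 3 x 2 catheters

    def test_noise_free_study_reproduces_model_predictions(self, pop):
        from dataclasses import replace

        p0 = replace(
            pop.without_variability(),
            sigma_cv={"plasma": 0.0, "microdialysate": 0.0, "retrodialysate": 0.0},
        )
        cohort, df = generate_study(p0, StudyDesign(), seed=2)
        sub = df[df["ID"] == cohort.subjects[0].subject_id]
        typ = apply_covariate_model(p0, cohort.subjects[0])
        from cefazolin_pk import DosingRegimen, solve_unbound, bind_total

        grid = np.linspace(0, 8.75, 1751)
        prof = solve_unbound(typ, DosingRegimen.with_redose(2000.0), grid)
        pt = sub[(sub["EVID"] == 0) & (sub["DVID"] == 1)]
        for _, row in pt.iterrows():
            cu = np.interp(row["TIME"], grid, prof.cu_plasma)
            assert row["DV"] == pytest.approx(
                float(bind_total(cu, typ.bmax, typ.kd)), rel=1e-9
            )
        # noiseless unbound <= total at matching times (binding adds mass)
        pu = sub[(sub["EVID"] == 0) & (sub["DVID"] == 2)]
        merged = pu.merge(pt, on="TIME", suffixes=("_u", "_t"))
        assert (merged["DV_u"] <= merged["DV_t"]).all()

    def test_plasma_residual_cv_matches_truth(self, pop):
        # with interindividual variability switched off, the spread of
        # observed/predicted plasma ratios is pure residual error
        design = StudyDesign(n_obese=60, n_nonobese=60)
        cohort, df = generate_study(pop.without_variability(), design, seed=8)
        from cefazolin_pk.estimation import build_groups, theta_from_population

        g = build_groups(df)[0]
        theta = theta_from_population(pop.without_variability())
        out = g._forward(theta, np.zeros((g.n, 8)))
        ratios = np.exp(g.y_log[:, :12] - out["lp_plasma"]).ravel()
        cv = 100 * ratios.std() / ratios.mean()
        assert cv == pytest.approx(35.7, abs=2.0)

    def test_recovery_cap_is_smooth_and_bounded(self):
        x = np.linspace(0.01, 5, 500)
        y = soft_cap_recovery(x)
        assert np.all(np.diff(y) > 0)
        assert np.all(y < 0.951)
        assert soft_cap_recovery(0.3) == pytest.approx(0.3, rel=1e-4)


class TestDatasetFormat:
    def test_roundtrip_bit_identical(self, study, tmp_path):
        _, df = study
        path = tmp_path / "data.csv"
        write_dataset(df, path)
        back = read_dataset(path)
        pd.testing.assert_frame_equal(df.reset_index(drop=True), back)

    def test_validation_rejects_missing_dose(self, study):
        _, df = study
        broken = df[df["EVID"] == 0]
        with pytest.raises(DatasetError):
            validate_dataset(broken)

    def test_validation_rejects_unknown_dvid(self, study):
        _, df = study
        broken = df.copy()
        broken.loc[broken["EVID"] == 0, "DVID"] = 9
        with pytest.raises(DatasetError):
            validate_dataset(broken)

    def test_validation_rejects_bad_interval(self, study):
        _, df = study
        broken = df.copy()
        dial = broken["DVID"] == 3
        broken.loc[dial, "IEND"] = broken.loc[dial, "ISTART"] - 0.1
        with pytest.raises(DatasetError):
            validate_dataset(broken)
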