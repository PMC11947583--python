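"""Likelihood machinery and the population fit."""

import numpy as np
import pytest

from cefazolin_pk import PopulationParameters, StudyDesign
from cefazolin_pk.covariates import apply_covariate_model
from cefazolin_pk.estimation import (
    FitSpecification,
    build_groups,
    fit,
    individual_loglik,
    marginal_loglik,
    theta_from_population,
)
from cefazolin_pk.study import generate_study


@pytest.fixture(scope="module")
def truth(pop):
    return theta_from_population(pop)


@pytest.fixture(scope="module")
def group(study):
    _, dataset = study
    (g,) = build_groups(dataset)
    return g


class TestLikelihoodSurface:
    def test_batched_matches_reference_per_subject(self, pop, study, truth, group):
        """The vectorized likelihood equals the plain per-record implementation."""
        cohort, dataset = study
        out = group._forward(truth, np.zeros((group.n, 8)))
        sigmas = {k: truth["sigma_" + k]
                  for k in ("plasma", "microdialysate", "retrodialysate")}
        for i in (0, 7, 13, 29):
            cov = cohort.subjects[i]
            assert group.ids[i] == cov.subject_id
            typ = apply_covariate_model(pop, cov)
            params = dict(
                cl=typ.cl, v1=typ.v1, q=typ.q, v2=typ.v2, bmax=typ.bmax,
                kd=typ.kd, tf=typ.tf,
                rr_cath={c: pop.rr_for_group(cov.obese) for c in (1, 2)},
            )
            ref = individual_loglik(
                params, dataset[dataset["ID"] == cov.subject_id], sigmas
            )
            assert -out["nll"][i] == pytest.approx(ref, abs=2e-3)

    def test_empty_subject_contributes_nothing(self, pop, study, truth):
        from cefazolin_pk.covariates import PatientCovariates

        _, dataset = study
        sub = dataset[dataset["ID"] == "S001"]
        doses_only = sub[sub["EVID"] == 1]
        cov = PatientCovariates(subject_id="x", sex="female", age=45, tbw=80,
                                lbw=50, fm=30, bmi=30)
        typ = apply_covariate_model(pop, cov)
        sigmas = {k: truth["sigma_" + k]
                  for k in ("plasma", "microdialysate", "retrodialysate")}
        params = dict(cl=typ.cl, v1=typ.v1, q=typ.q, v2=typ.v2, bmax=typ.bmax,
                      kd=typ.kd, tf=typ.tf, rr_cath={1: 0.4, 2: 0.4})
        assert individual_loglik(params, doses_only, sigmas) == 0.0

    def test_inner_gradient_matches_finite_differences(self, truth, group):
        active = list(range(8))
        prior_inv = 1.0 / group._omega_vector(truth)[active] ** 2
        rng = np.random.default_rng(3)
        eta = rng.normal(0, 0.2, size=(group.n, 8))
        grad, _ = group._grad_hess(truth, eta, active, prior_inv)

        def joint(e):
            pen = 0.5 * np.sum(e[:, active] ** 2 * prior_inv, axis=-1)
            return group._data_nll(truth, e) + pen

        h = 1e-6
        for (i, k) in [(0, 0), (5, 4), (12, 6), (29, 7)]:
            ep, em = eta.copy(), eta.copy()
            ep[i, k] += h
            em[i, k] -= h
            fd = (joint(ep)[i] - joint(em)[i]) / (2 * h)
            assert grad[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_subject_order_invariance(self, pop, truth):
        _, dataset = generate_study(pop, StudyDesign(n_obese=3, n_nonobese=3), seed=55)
        forward = marginal_loglik(truth, dataset)
        ids = dataset["ID"].unique()[::-1]
        shuffled = (
            dataset.set_index("ID").loc[ids].reset_index()
        )
        assert marginal_loglik(truth, shuffled) == pytest.approx(forward, abs=1e-6)

    def test_laplace_agrees_with_monte_carlo(self, pop, truth):
        _, dataset = generate_study(pop, StudyDesign(n_obese=4, n_nonobese=4), seed=66)
        lap = marginal_loglik(truth, dataset, method="laplace")
        mc = marginal_loglik(
            truth, dataset, method="mc",
            rng=np.random.default_rng(1), n_draws=30_000,
        )
        # plain MC at 3e4 draws carries a few-tenths SE on an 8-d integral
        assert lap == pytest.approx(mc, abs=0.05 * abs(mc))

    def test_single_eta_matches_dense_grid_quadrature(self, pop, truth):
        """1-d random effect: Laplace vs brute-force trapezoid integration."""
        from dataclasses import replace

        p1 = replace(
            pop,
            omega_cv={"cl": 25.0, "v1": 0.0, "q": 0.0, "v2": 0.0, "bmax": 0.0,
                      "rr": 0.0},
            catheter_cv={"intercatheter": 0.0, "intracatheter": 0.0},
        )
        cohort, dataset = generate_study(p1, StudyDesign(n_obese=1, n_nonobese=1),
                                         seed=9)
        th = theta_from_population(p1)
        th["omega_cath"] = 1e-12
        (g,) = build_groups(dataset)
        lap = -g.laplace(th, None)[0]
        quad = -g.quadrature_1d(th)

        # dense-grid oracle over the single active eta (clearance)
        omega = th["omega_cl"]
        grid = np.linspace(-5 * omega, 5 * omega, 801)
        total = 0.0
        sigmas = {k: th["sigma_" + k]
                  for k in ("plasma", "microdialysate", "retrodialysate")}
        for cov in cohort:
            typ = apply_covariate_model(p1, cov)
            lls = []
            for etacl in grid:
                params = dict(
                    cl=typ.cl * np.exp(etacl), v1=typ.v1, q=typ.q, v2=typ.v2,
                    bmax=typ.bmax, kd=typ.kd, tf=typ.tf,
                    rr_cath={c: p1.rr_for_group(cov.obese) for c in (1, 2)},
                )
                lls.append(
                    individual_loglik(
                        params, dataset[dataset["ID"] == cov.subject_id], sigmas
                    )
                )
            dens = np.exp(np.array(lls)) * np.exp(-0.5 * (grid / omega) ** 2) / (
                omega * np.sqrt(2 * np.pi)
            )
            total += np.log(np.trapezoid(dens, grid))
        # adaptive quadrature is effectively exact in one dimension
        assert quad == pytest.approx(total, abs=1e-3)
        # the Laplace approximation carries a small, documented error
        assert lap == pytest.approx(total, abs=0.05)


class TestFit:
    def test_noiseless_clearance_identified_exactly(self, pop):
        from dataclasses import replace

        p0 = replace(
            pop.without_variability(),
            sigma_cv={"plasma": 1e-4, "microdialysate": 1e-4,
                      "retrodialysate": 1e-4},
        )
        _, dataset = generate_study(p0, StudyDesign(n_obese=2, n_nonobese=2), seed=4)
        truth = theta_from_population(p0)
        init = dict(truth)
        init["cl"] = 10.0
        init["omega_cl"] = 0.01
        spec = FitSpecification(estimate=("cl",), init=init, maxiter=60)
        res = fit(dataset, spec)
        assert res.estimates["cl"] == pytest.approx(17.9, rel=1e-3)
        assert res.converged

    def test_objective_prefers_truth_over_perturbed_clearance(self, pop, truth):
        _, dataset = generate_study(pop, StudyDesign(), seed=12)
        at_truth = marginal_loglik(truth, dataset)
        perturbed = dict(truth)
        perturbed["cl"] = 2.0 * truth["cl"]
        assert at_truth > marginal_loglik(perturbed, dataset)

    def test_rejects_unknown_parameter_names(self):
        with pytest.raises(ValueError):
            FitSpecification(estimate=("cl", "not_a_parameter"))

    def test_rejects_invalid_initial_values(self):
        with pytest.raises(ValueError):
            FitSpecification(init={"cl": -3.0})
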