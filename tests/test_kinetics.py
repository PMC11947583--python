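"""Two-compartment solver, saturable binding and the dialysate map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from cefazolin_pk import (
    DosingRegimen,
    IndividualParameters,
    bind_total,
    dialysate_concentration,
    solve_unbound,
    unbind,
)
from cefazolin_pk.kinetics import (
    BiexponentialSolution,
    ModelSpecificationError,
    SimulatedProfile,
)

TYPICAL = IndividualParameters(cl=17.9, v1=22.9, q=56.8, v2=34.3)
TWO_G = DosingRegimen.with_redose(2000.0, None)


def _rate_matrix(p):
    return np.array(
        [[-(p.cl + p.q) / p.v1, p.q / p.v2], [p.q / p.v1, -p.q / p.v2]]
    )


def _expm_oracle(p, regimen, times):
    """Independent matrix-exponential solution: A(t) piecewise via expm."""
    K = _rate_matrix(p)
    Kinv = np.linalg.inv(K)
    out = np.zeros((len(times), 2))
    for i, t in enumerate(times):
        A = np.zeros(2)
        t0 = 0.0
        changes = sorted(
            {0.0, t} | {ev.start for ev in regimen.events} | {ev.end for ev in regimen.events}
        )
        for a, b in zip(changes, changes[1:]):
            if a >= t:
                break
            b = min(b, t)
            rate = sum(ev.rate for ev in regimen.events if ev.start <= a < ev.end)
            u = np.array([rate, 0.0])
            E = expm(K * (b - a))
            A = E @ A + Kinv @ (E - np.eye(2)) @ u
        out[i] = A
    return out


def _random_params(rng):
    return IndividualParameters(
        cl=rng.uniform(5, 40),
        v1=rng.uniform(8, 60),
        q=rng.uniform(10, 120),
        v2=rng.uniform(10, 90),
    )


class TestSolver:
    def test_zero_before_dosing(self):
        prof = solve_unbound(TYPICAL, TWO_G, np.linspace(0, 8, 81))
        assert prof.cu_plasma[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.c2[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_matrix_exponential(self):
        rng = np.random.default_rng(7)
        times = np.array([0.25, 0.5, 1.0, 2.5, 4.0, 6.0, 8.0])
        regimen = DosingRegimen.with_redose(2000.0, 4.0)
        for _ in range(10):
            p = _random_params(rng)
            prof = solve_unbound(p, regimen, times)
            ref = _expm_oracle(p, regimen, times)
            assert np.allclose(prof.cu_plasma, ref[:, 0] / p.v1, rtol=1e-9)
            assert np.allclose(prof.c2, ref[:, 1] / p.v2, rtol=1e-9)

    def test_matches_numerical_integration(self):
        p = TYPICAL
        regimen = DosingRegimen.with_redose(2000.0, 4.0)

        def rhs(t, y):
            rate = sum(ev.rate for ev in regimen.events if ev.start <= t < ev.end)
            a = (p.cl + p.q) / p.v1
            return [rate - a * y[0] + p.q / p.v2 * y[1],
                    p.q / p.v1 * y[0] - p.q / p.v2 * y[1]]

        times = np.linspace(0, 8, 33)
        num = solve_ivp(rhs, (0, 8), [0, 0], t_eval=times, rtol=1e-10, atol=1e-10,
                        max_step=0.1)
        prof = solve_unbound(p, regimen, times)
        assert np.allclose(prof.cu_plasma[1:], num.y[0, 1:] / p.v1, rtol=1e-6)

    def test_superposition_doubling_doses(self):
        times = np.linspace(0, 8, 161)
        single = solve_unbound(TYPICAL, DosingRegimen.with_redose(1000.0, 3.0), times)
        double = solve_unbound(TYPICAL, DosingRegimen.with_redose(2000.0, 3.0), times)
        assert np.allclose(2 * single.cu_plasma, double.cu_plasma, rtol=1e-12)

    def test_mass_balance(self):
        rng = np.random.default_rng(11)
        times = np.linspace(0.01, 10, 200)
        for _ in range(5):
            p = _random_params(rng)
            sol = BiexponentialSolution(p.cl, p.v1, p.q, p.v2, TWO_G, 10.0)
            a1, a2 = sol.amounts(times)
            eliminated = sol.eliminated(times)
            dosed = np.minimum(times, 0.5) / 0.5 * 2000.0
            balance = a1 + a2 + eliminated
            assert np.allclose(balance, dosed, rtol=1e-6)

    def test_isf_peak_lags_plasma_peak(self):
        times = np.linspace(0, 8, 801)
        prof = solve_unbound(TYPICAL, TWO_G, times)
        assert times[np.argmax(prof.c_isf)] >= times[np.argmax(prof.cu_plasma)]

    def test_exact_interval_average_matches_trapezoid(self):
        times = np.linspace(0, 9, 1801)
        prof = solve_unbound(TYPICAL, TWO_G, times)
        sol = BiexponentialSolution(TYPICAL.cl, TYPICAL.v1, TYPICAL.q, TYPICAL.v2,
                                    TWO_G, 9.0)
        intervals = np.array([[0.0, 0.5], [2.0, 3.0], [7.0, 8.0], [8.0, 8.25]])
        _, c2bar = sol.interval_average_concentrations(intervals)
        for (lo, hi), exact in zip(intervals, c2bar):
            trap = dialysate_concentration(prof, (lo, hi), rr=1.0, min_points=400)
            assert trap == pytest.approx(TYPICAL.tf * exact, rel=2e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            IndividualParameters(cl=-1, v1=20, q=50, v2=30)
        with pytest.raises(ModelSpecificationError):
            solve_unbound(TYPICAL, TWO_G, np.array([0.5, 0.25]))
        with pytest.raises(ModelSpecificationError):
            DosingRegimen.from_tuples([(0.0, -5.0, 0.5)])


class TestBinding:
    def test_half_saturation_identity(self):
        # at cu = Kd, half of the binding sites are occupied
        total = bind_total(65.3, bmax=247.0, kd=65.3)
        assert total - 65.3 == pytest.approx(123.5)
        assert total == pytest.approx(188.8)

    def test_zero_and_saturation_limits(self):
        assert bind_total(0.0, 247.0, 65.3) == 0.0
        bound = bind_total(1e9, 247.0, 65.3) - 1e9
        assert bound == pytest.approx(247.0, rel=1e-6)

    def test_unbind_inverts_half_saturation(self):
        assert unbind(188.8, 247.0, 65.3) == pytest.approx(65.3, rel=1e-10)
        assert unbind(0.0, 247.0, 65.3) == 0.0

    def test_round_trip_on_random_concentrations(self, rng):
        cu = rng.uniform(1e-6, 500.0, size=1000)
        back = unbind(np.asarray(bind_total(cu, 247.0, 65.3)), 247.0, 65.3)
        assert np.allclose(back, cu, rtol=1e-10)

    @given(st.floats(0.01, 1e4))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_property(self, c_total):
        cu = unbind(c_total, 247.0, 65.3)
        assert float(bind_total(cu, 247.0, 65.3)) == pytest.approx(
            c_total, rel=1e-10
        )

    def test_unbound_fraction_increases_with_concentration(self):
        cu = np.linspace(0.1, 400, 300)
        ratio = np.asarray(bind_total(cu, 247.0, 65.3)) / cu
        assert np.all(np.diff(ratio) < 0)  # total/unbound falls as binding saturates


class TestDialysate:
    def _flat_profile(self, value, t_end=8.0):
        t = np.linspace(0, t_end, 81)
        return SimulatedProfile(times=t, cu_plasma=t * 0, c2=t * 0,
                                c_isf=np.full_like(t, value), c_total=t * 0)

    def test_microdialysis_flat_profile(self):
        prof = self._flat_profile(10.0)
        assert dialysate_concentration(prof, (1.0, 2.0), rr=0.5) == pytest.approx(5.0)

    def test_retrodialysis_into_drug_free_tissue(self):
        prof = self._flat_profile(0.0)
        out = dialysate_concentration(prof, (0.0, 0.25), rr=0.233, perfusate=100.0)
        assert out == pytest.approx(76.7)

    def test_linear_ramp_exact_average(self):
        t = np.linspace(0, 8, 9)
        prof = SimulatedProfile(times=t, cu_plasma=t * 0, c2=t * 0,
                                c_isf=t.copy(), c_total=t * 0)
        assert dialysate_concentration(prof, (2.0, 3.0), rr=1.0) == pytest.approx(2.5)

    def test_recovery_outside_unit_interval_rejected(self):
        prof = self._flat_profile(1.0)
        from cefazolin_pk.kinetics import CalibrationError

        for rr in (0.0, -0.5, 1.2):
            with pytest.raises(CalibrationError):
                dialysate_concentration(prof, (0, 1), rr=rr)
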