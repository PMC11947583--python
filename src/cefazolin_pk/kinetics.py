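"""Two-compartment unbound kinetics, saturable binding, dialysate mapping.

The disposition system is linear in unbound-referenced amounts::

    dA1/dt = input(t) - (CL+Q)/V1 * A1 + Q/V2 * A2
    dA2/dt =            Q/V1 * A1     - Q/V2 * A2

with zero-order infusion input. Within every interval of constant input rate
the solution is biexponential; this module evaluates it (and its exact time
integral, needed for dialysate interval averages and mass balance) in closed
form from the eigendecomposition of the 2x2 rate matrix. All routines accept
parameter arrays with arbitrary leading batch dimensions, and complex dtypes,
so that population simulation and complex-step differentiation run through
the same code path.

Saturable plasma binding maps unbound to total central concentration through
a single-site Langmuir term, ``c_total = cu + bmax*cu/(kd + cu)``, applied at
the observation level only. ISF concentration is ``tf`` times the
peripheral concentration; dialysate concentrations are relative-recovery
weighted interval averages of ISF (plus perfusate carry-over during
retrodialysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ModelSpecificationError(ValueError):
    """Raised for invalid structural parameters, regimens or grids."""


# ---------------------------------------------------------------------------
# dosing regimen


@dataclass(frozen=True)
class InfusionEvent:
    start: float      # h
    amount: float     # mg
    duration: float   # h

    @property
    def rate(self) -> float:  # mg/h
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DosingRegimen:
    """A time-sorted sequence of zero-order i.v. infusions."""

    events: tuple[InfusionEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ModelSpecificationError("regimen has no dosing events")
        for ev in self.events:
            if ev.amount <= 0 or ev.duration <= 0 or ev.start < 0:
                raise ModelSpecificationError(f"invalid infusion event {ev}")
        starts = [ev.start for ev in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ModelSpecificationError("events must be time-sorted")

    @classmethod
    def from_tuples(cls, events: Sequence[tuple[float, float, float]]) -> "DosingRegimen":
        return cls(tuple(InfusionEvent(*ev) for ev in sorted(events)))

    @classmethod
    def with_redose(
        cls, dose_mg: float, redose_time: float | None = None, duration: float = 0.5
    ) -> "DosingRegimen":
        """Initial dose at t=0 plus an optional identical redose."""
        events = [InfusionEvent(0.0, dose_mg, duration)]
        if redose_time is not None:
            events.append(InfusionEvent(redose_time, dose_mg, duration))
        return cls(tuple(events))

    @classmethod
    def repeated(
        cls,
        dose_mg: float,
        interval: float,
        t_end: float = 8.0,
        duration: float = 0.5,
    ) -> "DosingRegimen":
        """Identical infusions at 0, interval, 2*interval, ... strictly before t_end.

        This is the prophylactic "dose plus redosing every `interval` hours"
        pattern: a 1 g q3h regimen over 8 h doses at 0, 3 and 6 h, while q4h
        doses at 0 and 4 h.
        """
        if interval <= 0:
            raise ModelSpecificationError("dosing interval must be positive")
        starts = np.arange(0.0, t_end - 1e-9, interval)
        return cls(tuple(InfusionEvent(float(s), dose_mg, duration) for s in starts))

    def total_dose(self) -> float:
        return sum(ev.amount for ev in self.events)

    def breakpoints(self, t_max: float) -> tuple[np.ndarray, np.ndarray]:
        """Segment start times and the constant total rate within each segment."""
        pts = {0.0, float(t_max)}
        for ev in self.events:
            pts.update((ev.start, ev.end))
        starts = np.array(sorted(p for p in pts if p < t_max))
        rates = np.zeros_like(starts)
        for ev in self.events:
            active = (starts >= ev.start) & (starts < ev.end)
            rates[active] += ev.rate
        return starts, rates


# ---------------------------------------------------------------------------
# closed-form piecewise-biexponential solution


class BiexponentialSolution:
    """Closed-form solution of the two-compartment system for one regimen.

    Parameters may be scalars or broadcastable arrays (batch of subjects,
    complex-step perturbations, ...). States and their running time-integrals
    are evaluated exactly at arbitrary nonnegative times up to ``t_max``.
    """

    def __init__(self, cl, v1, q, v2, regimen: DosingRegimen, t_max: float):
        cl, v1, q, v2 = np.broadcast_arrays(
            np.asarray(cl), np.asarray(v1), np.asarray(q), np.asarray(v2)
        )
        for name, arr in (("cl", cl), ("v1", v1), ("q", q), ("v2", v2)):
            if np.any(arr.real <= 0):
                raise ModelSpecificationError(f"{name} must be positive")
        self.cl, self.v1, self.q, self.v2 = cl, v1, q, v2
        self.t_max = float(t_max)
        last_end = max(ev.end for ev in regimen.events)
        if last_end > self.t_max:
            self.t_max = last_end

        a = (cl + q) / v1
        b = q / v2
        c = q / v1
        disc = (a - b) ** 2 + 4.0 * b * c  # always > 0: distinct real eigenvalues
        sq = np.sqrt(disc)
        lam1 = 0.5 * (-(a + b) + sq)
        lam2 = 0.5 * (-(a + b) - sq)
        self._a, self._b = a, b
        self.lam1, self.lam2 = lam1, lam2

        starts, rates = regimen.breakpoints(self.t_max)
        self._seg_starts = starts
        self._seg_rates = rates

        # per segment: steady-state offset, modal coefficients, and the
        # accumulated integrals of A1/A2 at the segment start
        shape = cl.shape
        dtype = np.result_type(cl, float)
        n_seg = len(starts)
        self._ss1 = np.empty((n_seg,) + shape, dtype=dtype)
        self._ss2 = np.empty_like(self._ss1)
        self._m1 = np.empty_like(self._ss1)
        self._m2 = np.empty_like(self._ss1)
        self._int1_0 = np.empty_like(self._ss1)
        self._int2_0 = np.empty_like(self._ss1)

        a1 = np.zeros(shape, dtype=dtype)
        a2 = np.zeros(shape, dtype=dtype)
        int1 = np.zeros(shape, dtype=dtype)
        int2 = np.zeros(shape, dtype=dtype)
        for k, (t0, rate) in enumerate(zip(starts, rates)):
            ss1 = rate * v1 / cl
            ss2 = rate * v2 / cl
            d1 = a1 - ss1
            d2 = a2 - ss2
            denom = b * (lam2 - lam1)
            m1 = (d1 * (a + lam2) - b * d2) / denom
            m2 = (b * d2 - d1 * (a + lam1)) / denom
            self._ss1[k], self._ss2[k] = ss1, ss2
            self._m1[k], self._m2[k] = m1, m2
            self._int1_0[k], self._int2_0[k] = int1, int2
            # advance state and integrals to the end of the segment
            t_end = starts[k + 1] if k + 1 < n_seg else self.t_max
            dt = t_end - t0
            e1 = np.exp(lam1 * dt)
            e2 = np.exp(lam2 * dt)
            a1 = ss1 + b * (m1 * e1 + m2 * e2)
            a2 = ss2 + m1 * (a + lam1) * e1 + m2 * (a + lam2) * e2
            int1 = int1 + ss1 * dt + b * (m1 * (e1 - 1) / lam1 + m2 * (e2 - 1) / lam2)
            int2 = (
                int2
                + ss2 * dt
                + m1 * (a + lam1) * (e1 - 1) / lam1
                + m2 * (a + lam2) * (e2 - 1) / lam2
            )

    def _segment_index(self, times: np.ndarray) -> np.ndarray:
        return np.clip(
            np.searchsorted(self._seg_starts, times, side="right") - 1,
            0,
            len(self._seg_starts) - 1,
        )

    def amounts(self, times) -> tuple[np.ndarray, np.ndarray]:
        """Amounts (A1, A2) at ``times``; output shape = batch + times.shape."""
        times = np.asarray(times, dtype=float)
        if np.any(times < 0) or np.any(times > self.t_max + 1e-12):
            raise ModelSpecificationError("evaluation times outside [0, t_max]")
        idx = self._segment_index(times)
        dt = times - self._seg_starts[idx]
        lam1 = self.lam1[..., None]
        lam2 = self.lam2[..., None]
        a = self._a[..., None]
        b = self._b[..., None]
        flat = idx.ravel()
        sel = lambda arr: np.moveaxis(arr[flat], 0, -1).reshape(
            arr.shape[1:] + times.shape
        )
        e1 = np.exp(lam1 * dt.ravel())
        e2 = np.exp(lam2 * dt.ravel())
        m1, m2 = sel(self._m1), sel(self._m2)
        a1 = sel(self._ss1) + b * (m1 * e1 + m2 * e2)
        a2 = sel(self._ss2) + m1 * (a + lam1) * e1 + m2 * (a + lam2) * e2
        return a1, a2

    def concentrations(self, times) -> tuple[np.ndarray, np.ndarray]:
        """Unbound central and peripheral concentrations (cu, c2) at ``times``."""
        a1, a2 = self.amounts(times)
        return a1 / self.v1[..., None], a2 / self.v2[..., None]

    def integral_amounts(self, times) -> tuple[np.ndarray, np.ndarray]:
        """Exact running integrals (∫A1 dt, ∫A2 dt) from 0 to each time."""
        times = np.asarray(times, dtype=float)
        idx = self._segment_index(times)
        dt = times - self._seg_starts[idx]
        lam1 = self.lam1[..., None]
        lam2 = self.lam2[..., None]
        a = self._a[..., None]
        b = self._b[..., None]
        flat = idx.ravel()
        sel = lambda arr: np.moveaxis(arr[flat], 0, -1).reshape(
            arr.shape[1:] + times.shape
        )
        e1m = np.expm1(lam1 * dt.ravel())
        e2m = np.expm1(lam2 * dt.ravel())
        m1, m2 = sel(self._m1), sel(self._m2)
        i1 = sel(self._int1_0) + sel(self._ss1) * dt.ravel() + b * (
            m1 * e1m / lam1 + m2 * e2m / lam2
        )
        i2 = (
            sel(self._int2_0)
            + sel(self._ss2) * dt.ravel()
            + m1 * (a + lam1) * e1m / lam1
            + m2 * (a + lam2) * e2m / lam2
        )
        return i1, i2

    def interval_average_concentrations(
        self, intervals: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Exact time-averages of (cu, c2) over ``intervals`` of shape (K, 2)."""
        intervals = np.asarray(intervals, dtype=float)
        widths = intervals[:, 1] - intervals[:, 0]
        if np.any(widths <= 0):
            raise ModelSpecificationError("intervals must have positive width")
        i1_lo, i2_lo = self.integral_amounts(intervals[:, 0])
        i1_hi, i2_hi = self.integral_amounts(intervals[:, 1])
        cu_bar = (i1_hi - i1_lo) / widths / self.v1[..., None]
        c2_bar = (i2_hi - i2_lo) / widths / self.v2[..., None]
        return cu_bar, c2_bar

    def eliminated(self, times) -> np.ndarray:
        """Cumulative amount eliminated, CL*∫cu dt, at each time."""
        i1, _ = self.integral_amounts(times)
        return self.cl[..., None] * i1 / self.v1[..., None]


# ---------------------------------------------------------------------------
# saturable plasma binding


def bind_total(cu, bmax: float, kd: float):
    """Total plasma concentration from unbound: cu + bmax*cu/(kd + cu)."""
    cu = np.asarray(cu)
    if np.any(cu.real < -1e-9 * float(kd)):
        raise ValueError("unbound concentration must be nonnegative")
    if not np.iscomplexobj(cu):
        cu = np.maximum(cu, 0.0)   # clip solver round-off at t ~ 0
    return cu + bmax * cu / (kd + cu)


def unbind(c_total, bmax: float, kd: float):
    """Unbound concentration from total: nonnegative root of the binding quadratic.

    Solves cu**2 + (kd + bmax - c_total)*cu - kd*c_total = 0 with the
    numerically stable quadratic formula (no cancellation for either sign
    of the linear coefficient).
    """
    c_total = np.asarray(c_total, dtype=float)
    if np.any(c_total < 0):
        raise ValueError("total concentration must be nonnegative")
    p = kd + bmax - c_total
    disc = np.sqrt(p * p + 4.0 * kd * c_total)
    cu = np.where(p <= 0, 0.5 * (-p + disc), 2.0 * kd * c_total / (p + disc))
    return cu


# ---------------------------------------------------------------------------
# simulated profile container and dialysate observation map


@dataclass
class SimulatedProfile:
    """Concentration trajectories of one subject on a common time grid."""

    times: np.ndarray          # h
    cu_plasma: np.ndarray      # mg/L, unbound central
    c2: np.ndarray             # mg/L, peripheral
    c_isf: np.ndarray = field(default=None)   # mg/L, tf * c2
    c_total: np.ndarray = field(default=None) # mg/L, via binding map

    @classmethod
    def from_states(cls, times, cu, c2, tf: float, bmax: float, kd: float):
        # clip closed-form round-off (~1e-17 at t=0) to keep concentrations >= 0
        cu = np.maximum(np.asarray(cu, dtype=float), 0.0)
        c2 = np.maximum(np.asarray(c2, dtype=float), 0.0)
        return cls(
            times=np.asarray(times, dtype=float),
            cu_plasma=cu,
            c2=c2,
            c_isf=tf * c2,
            c_total=np.asarray(bind_total(cu, bmax, kd), dtype=float),
        )


def solve_unbound(params, regimen: DosingRegimen, times) -> SimulatedProfile:
    """Solve the model for one individual on a strictly increasing time grid."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ModelSpecificationError("times must be 1-d, nonnegative, strictly increasing")
    sol = BiexponentialSolution(
        params.cl, params.v1, params.q, params.v2, regimen, t_max=float(times[-1])
    )
    cu, c2 = sol.concentrations(times)
    return SimulatedProfile.from_states(
        times, cu, c2, tf=params.tf, bmax=params.bmax, kd=params.kd
    )


class CalibrationError(ValueError):
    """Raised for relative-recovery values outside (0, 1]."""


def dialysate_concentration(
    profile: SimulatedProfile,
    interval: tuple[float, float],
    rr: float,
    perfusate: float = 0.0,
    min_points: int = 20,
) -> float:
    """Dialysate concentration over a collection interval.

    Integrated dialysate-based approach: the catheter effluent concentration
    equals ``perfusate + rr * (time-average of c_isf - perfusate)``, where
    the average is a trapezoidal integral of the ISF trajectory over the
    interval (the profile is resampled so at least ``min_points`` grid points
    cover the interval). ``perfusate`` is 0 for microdialysis sampling and
    positive during retrodialysis calibration.
    """
    t_lo, t_hi = float(interval[0]), float(interval[1])
    if not t_hi > t_lo >= 0:
        raise ValueError(f"invalid interval {interval}")
    if not 0 < rr <= 1:
        raise CalibrationError(f"relative recovery {rr} outside (0, 1]")
    if perfusate < 0:
        raise ValueError("perfusate concentration must be nonnegative")
    inner = profile.times[(profile.times > t_lo) & (profile.times < t_hi)]
    grid = np.union1d(np.linspace(t_lo, t_hi, min_points + 1), inner)
    c = np.interp(grid, profile.times, profile.c_isf)
    mean_isf = np.trapezoid(c, grid) / (t_hi - t_lo)
    return perfusate + rr * (mean_isf - perfusate)
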