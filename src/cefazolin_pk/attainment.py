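"""Target-attainment metrics: fT>MIC, PTA and CFR.

The pharmacodynamic target is unbound concentration above the MIC for 100%
of the evaluation window (fT>MIC = 100%). The window runs from the end of
the first infusion (0.5 h by default) to 8 h: concentration is zero at the
start of the infusion, so a window anchored at t=0 could never be attained.
Ties at exactly the MIC count as non-attainment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import ProfileEnsemble

#: evaluation window (h) for the fT>MIC = 100% target
DEFAULT_WINDOW: tuple[float, float] = (0.5, 8.0)

#: doubling-dilution MIC grid up to the 4 mg/L clinical breakpoint
DEFAULT_MIC_GRID: tuple[float, ...] = (0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0)

#: PTA/CFR adequacy threshold
ADEQUACY_THRESHOLD = 0.90


@dataclass(frozen=True)
class MICDistribution:
    """MIC values with relative frequencies, for CFR weighting."""

    entries: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        mics = [m for m, _ in self.entries]
        freqs = [f for _, f in self.entries]
        if not mics:
            raise ValueError("empty MIC distribution")
        if any(m <= 0 for m in mics) or any(np.diff(mics) <= 0):
            raise ValueError("MIC values must be positive and strictly increasing")
        if any(f < 0 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("frequencies must be nonnegative and sum to 1")

    @property
    def mics(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.entries)

    @classmethod
    def from_file(cls, path, sep: str = ",") -> "MICDistribution":
        """Read a two-column delimited file (mic, frequency)."""
        df = pd.read_csv(path, sep=sep)
        if df.shape[1] < 2:
            raise ValueError("MIC distribution file needs two columns (mic, frequency)")
        mic_col, freq_col = df.columns[:2]
        return cls(tuple(zip(df[mic_col].astype(float), df[freq_col].astype(float))))


@dataclass(frozen=True)
class PTAResult:
    mic: float
    pta: float
    n: int
    matrix: str

    @property
    def adequate(self) -> bool:
        return self.pta >= ADEQUACY_THRESHOLD


def ft_above_mic(
    times: np.ndarray,
    conc: np.ndarray,
    mic: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """Fraction of the window with concentration strictly above the MIC.

    Threshold crossings between grid points are located by linear
    interpolation, so the result is exact for piecewise-linear trajectories.
    """
    t_lo, t_hi = window
    if not t_hi > t_lo:
        raise ValueError("empty evaluation window")
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if t_lo < times[0] or t_hi > times[-1]:
        raise ValueError("window outside the simulated grid")
    t = np.union1d(times[(times > t_lo) & (times < t_hi)], [t_lo, t_hi])
    c = np.interp(t, times, conc)
    d = c - mic
    dt = np.diff(t)
    d0, d1 = d[:-1], d[1:]
    both_above = (d0 > 0) & (d1 > 0)
    cross = (d0 > 0) != (d1 > 0)
    # fraction of the sub-interval on the above-MIC side of the crossing
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d0 > 0, d0 / (d0 - d1), d1 / (d1 - d0))
    above = np.sum(dt[both_above]) + np.sum(dt[cross] * frac[cross])
    return float(above / (t_hi - t_lo))


def _window_trajectories(
    profiles: ProfileEnsemble | Iterable,
    matrix: str,
    window: tuple[float, float],
) -> np.ndarray:
    """Concentrations at every evaluated instant of the window, (n, k)."""
    if isinstance(profiles, ProfileEnsemble):
        times = profiles.times
        conc = profiles.trajectory(matrix)
    else:
        plist = list(profiles)
        times = plist[0].times
        attr = "cu_plasma" if matrix == "plasma_unbound" else "c_isf"
        conc = np.stack([getattr(p, attr) for p in plist])
    t_lo, t_hi = window
    if t_lo < times[0] or t_hi > times[-1]:
        raise ValueError("window outside the simulated grid")
    t = np.union1d(times[(times > t_lo) & (times < t_hi)], [t_lo, t_hi])
    interp = np.empty((conc.shape[0], len(t)))
    for i in range(conc.shape[0]):
        interp[i] = np.interp(t, times, conc[i])
    return interp


def pta(
    profiles: ProfileEnsemble | Iterable,
    mic: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    matrix: str = "plasma_unbound",
) -> PTAResult:
    """Probability of target attainment: share of subjects with fT>MIC = 100%."""
    conc = _window_trajectories(profiles, matrix, window)
    if conc.shape[0] < 1:
        raise ValueError("need at least one profile")
    attained = np.all(conc > mic, axis=1)
    return PTAResult(
        mic=float(mic),
        pta=float(np.mean(attained)),
        n=conc.shape[0],
        matrix=matrix,
    )


def pta_curve(
    profiles: ProfileEnsemble | Iterable,
    mics: Iterable[float] = DEFAULT_MIC_GRID,
    window: tuple[float, float] = DEFAULT_WINDOW,
    matrix: str = "plasma_unbound",
) -> dict[float, PTAResult]:
    """PTA across a MIC grid, reusing the interpolated trajectories."""
    conc = _window_trajectories(profiles, matrix, window)
    minima = conc.min(axis=1)
    out = {}
    for mic in mics:
        out[float(mic)] = PTAResult(
            mic=float(mic),
            pta=float(np.mean(minima > mic)),
            n=conc.shape[0],
            matrix=matrix,
        )
    return out


class MICCoverageError(KeyError):
    """Raised when a distribution MIC has no PTA value."""


def cfr(
    pta_by_mic: Mapping[float, "PTAResult | float"], dist: MICDistribution
) -> float:
    """Cumulative fraction of response: frequency-weighted average PTA."""
    missing = [m for m in dist.mics if m not in pta_by_mic]
    if missing:
        raise MICCoverageError(f"no PTA value for MIC(s) {missing}")
    total = 0.0
    for mic, freq in dist.entries:
        val = pta_by_mic[mic]
        total += freq * (val.pta if isinstance(val, PTAResult) else float(val))
    return total
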