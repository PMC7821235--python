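"""Analytic reference waveforms: monopolar (Stejskal-Tanner) and bipolar.

These fixtures serve as optimization baselines and as closed-form oracles
for the numerical encoding metrics.  Lobes are trapezoids described by
breakpoint lists; the attached "exact" metrics integrate the piecewise-linear
segments analytically (3-point Gauss-Legendre per segment, exact for the
quartic integrand of the b-value), independently of any sample grid.

Conventions
-----------
A lobe with amplitude ``g``, ramp time ``rise`` and duration ``delta`` has
footprint ``delta + rise`` and area ``g * delta`` (the common convention in
which the rectangular Stejskal-Tanner formulas hold with trapezoid
corrections ``b = gamma^2 g^2 [delta^2 (Delta - delta/3) + rise^3/30 -
delta rise^2/6]``).  ``Delta`` is the separation between lobe starts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import TimeGrid
from .units import GAMMA_H
from .waveform import EffectiveWaveform

__all__ = [
    "PGSEParams",
    "make_monopolar",
    "make_bipolar",
    "best_pgse",
    "stejskal_tanner_b",
    "trapezoid_pgse_b",
    "monopolar_m1",
    "exact_b_from_segments",
    "exact_moment_from_segments",
]


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def stejskal_tanner_b(g: float, delta: float, Delta: float,
                      gamma: float = GAMMA_H) -> float:
    """Rectangular-lobe PGSE b-value ``gamma^2 g^2 delta^2 (Delta - delta/3)``."""
    return gamma**2 * g**2 * delta**2 * (Delta - delta / 3.0)


def trapezoid_pgse_b(g: float, delta: float, Delta: float, rise: float,
                     gamma: float = GAMMA_H) -> float:
    """Trapezoid-lobe PGSE b-value with the standard ramp corrections."""
    return gamma**2 * g**2 * (delta**2 * (Delta - delta / 3.0)
                              + rise**3 / 30.0 - delta * rise**2 / 6.0)


def monopolar_m1(g: float, delta: float, Delta: float,
                 gamma: float = GAMMA_H) -> float:
    """|m1| of a monopolar pair: ``gamma g delta Delta`` (any lobe shape)."""
    return gamma * g * delta * Delta


# ---------------------------------------------------------------------------
# exact segment integration (grid-independent oracle)
# ---------------------------------------------------------------------------

_GL3_X = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GL3_W = np.array([5.0, 8.0, 5.0]) / 9.0


def exact_b_from_segments(t: np.ndarray, g: np.ndarray,
                          gamma: float = GAMMA_H) -> float:
    """b-value of a piecewise-linear effective gradient given by breakpoints.

    ``t`` (increasing) and ``g`` are 1D breakpoint arrays for a single axis.
    q(t) is integrated exactly segment by segment (quadratic per segment),
    then ``int q^2 dt`` is evaluated with 3-point Gauss-Legendre, which is
    exact for the quartic integrand.
    """
    t = np.asarray(t, float)
    g = np.asarray(g, float)
    q0 = 0.0
    total = 0.0
    for k in range(len(t) - 1):
        h = t[k + 1] - t[k]
        if h <= 0:
            continue
        a, b = g[k], g[k + 1]
        # q on segment: q0 + gamma*(a*s + (b-a) s^2/(2h)), s in [0, h]
        s = 0.5 * h * (_GL3_X + 1.0)
        qs = q0 + gamma * (a * s + (b - a) * s**2 / (2.0 * h))
        total += 0.5 * h * (_GL3_W * qs**2).sum()
        q0 += gamma * 0.5 * (a + b) * h
    return float(total)


def exact_moment_from_segments(t: np.ndarray, g: np.ndarray, n: int,
                               gamma: float = GAMMA_H) -> float:
    """``gamma int g(t) t^n dt`` for breakpoint-defined piecewise-linear g."""
    t = np.asarray(t, float)
    g = np.asarray(g, float)
    total = 0.0
    for k in range(len(t) - 1):
        h = t[k + 1] - t[k]
        if h <= 0:
            continue
        s = 0.5 * h * (_GL3_X + 1.0)
        ts = t[k] + s
        gs = g[k] + (g[k + 1] - g[k]) * s / h
        total += 0.5 * h * (_GL3_W * gs * ts**n).sum()
    return gamma * total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass
class PGSEParams:
    """Geometry of a pulsed-gradient pair rendered onto a :class:`TimeGrid`.

    ``delta`` is the area-equivalent lobe duration (area = g * delta),
    ``Delta`` the lobe-start separation (default: minimal, lobes hugging the
    refocusing gap) and ``rise_time`` the trapezoid ramp (default: one grid
    interval, i.e. as close to rectangular as the grid can represent).
    """

    g: float
    delta: float
    Delta: float | None = None
    rise_time: float | None = None
    grid: TimeGrid | None = None
    gamma: float = GAMMA_H

    def resolve(self, gap: float = 8.0e-3, dt: float = 1.0e-5,
                lobes_per_period: int = 1):
        """Fill in defaults; returns (grid, delta, Delta, rise)."""
        grid = self.grid
        if grid is None:
            rise = self.rise_time if self.rise_time is not None else dt
            foot = lobes_per_period * (self.delta + rise)
            d1 = foot if self.Delta is None else max(foot, self.Delta - gap)
            d2 = foot
            grid = TimeGrid.from_timings(d1, gap, d2, dt)
        rise = self.rise_time if self.rise_time is not None else grid.dt
        Delta = self.Delta
        if Delta is None:
            Delta = self.delta + rise + grid.gap
        return grid, self.delta, Delta, rise


def _snap(value: float, dt: float, name: str) -> int:
    k = round(value / dt)
    if abs(k * dt - value) > 1e-9 * max(1.0, abs(value)):
        raise ValueError(f"{name} = {value} is not aligned to the grid "
                         f"spacing {dt}")
    return k


def _render(grid: TimeGrid, breaks_t: np.ndarray, breaks_g: np.ndarray,
            axis: int, gamma: float) -> EffectiveWaveform:
    g = np.zeros((grid.n_samples, 3))
    g[:, axis] = np.interp(grid.times, breaks_t, breaks_g)
    return EffectiveWaveform(grid=grid, g=g, gamma=gamma)


def _lobe_breaks(t0: float, delta: float, rise: float, amp: float):
    """Breakpoints of one trapezoid lobe with footprint delta + rise."""
    return ([t0, t0 + rise, t0 + delta, t0 + delta + rise],
            [0.0, amp, amp, 0.0])


def _merge(segments):
    """Concatenate lobe breakpoints, padding zeros between them."""
    ts, gs = [0.0], [0.0]
    for bt, bg in segments:
        if bt[0] > ts[-1] + 1e-15:
            ts.append(bt[0])
            gs.append(0.0)
        ts.extend(bt[1:])
        gs.extend(bg[1:])
    return np.array(ts), np.array(gs)


def _close(ts, gs, tau):
    if ts[-1] < tau:
        ts = np.append(ts, tau)
        gs = np.append(gs, 0.0)
    return ts, gs


def make_monopolar(p: PGSEParams, axis: int = 0) -> EffectiveWaveform:
    """Monopolar (Stejskal-Tanner) pair on a spin-echo timeline.

    Both lobes have equal physical sign; in the effective convention the
    second lobe is negated, so ``m0 = 0`` by construction and
    ``|m1| = gamma g delta Delta``.  The rendered waveform carries the
    breakpoints on ``.segments`` for exact (grid-free) metric evaluation.
    """
    grid, delta, Delta, rise = p.resolve()
    foot = delta + rise
    _snap(delta, grid.dt, "delta")
    _snap(rise, grid.dt, "rise_time")
    _snap(Delta, grid.dt, "Delta")
    start1 = grid.delta1 - foot
    start2 = start1 + Delta
    if start1 < -1e-12:
        raise ValueError("first lobe does not fit in the first encoding period")
    if start2 < grid.delta1 + grid.gap - 1e-12:
        raise ValueError("Delta too small: second lobe overlaps the refocusing gap")
    if start2 + foot > grid.tau + 1e-12:
        raise ValueError("second lobe does not fit in the second encoding period")
    ts, gs = _merge([_lobe_breaks(start1, delta, rise, p.g),
                     _lobe_breaks(start2, delta, rise, -p.g)])
    ts, gs = _close(ts, gs, grid.tau)
    w = _render(grid, ts, gs, axis, p.gamma)
    w.segments = (ts, gs)
    return w


def make_bipolar(p: PGSEParams, axis: int = 0) -> EffectiveWaveform:
    """Velocity-compensated bipolar design: one +/- lobe pair per period.

    The second period's pair is reversed (effective convention), which
    cancels m1 exactly for any lobe shape while m0 vanishes per pair;
    m2 remains nonzero (velocity-only compensation).
    """
    grid, delta, _, rise = p.resolve(lobes_per_period=2)
    foot = delta + rise
    _snap(delta, grid.dt, "delta")
    _snap(rise, grid.dt, "rise_time")
    if 2 * foot > grid.delta1 + 1e-12 or 2 * foot > grid.delta2 + 1e-12:
        raise ValueError("bipolar pair does not fit in the encoding periods")
    start1 = grid.delta1 - 2 * foot
    start2 = grid.delta1 + grid.gap
    ts, gs = _merge([
        _lobe_breaks(start1, delta, rise, p.g),
        _lobe_breaks(start1 + foot, delta, rise, -p.g),
        _lobe_breaks(start2, delta, rise, -p.g),
        _lobe_breaks(start2 + foot, delta, rise, p.g),
    ])
    ts, gs = _close(ts, gs, grid.tau)
    w = _render(grid, ts, gs, axis, p.gamma)
    w.segments = (ts, gs)
    return w


def best_pgse(gmax: float, smax: float, grid: TimeGrid,
              gamma: float = GAMMA_H) -> EffectiveWaveform:
    """Maximal trapezoid PGSE under amplitude/slew bounds on a given grid.

    Lobes ramp at ``smax`` to ``gmax`` and fill the shorter encoding period;
    this is the classic single-axis baseline against which optimized
    waveforms are compared.
    """
    rise = max(grid.dt, np.ceil(gmax / smax / grid.dt) * grid.dt)
    foot = min(grid.delta1, grid.delta2)
    delta = foot - rise
    if delta <= 0:
        raise ValueError("encoding periods too short for a single ramp")
    Delta = foot + grid.gap  # second lobe starts right after the gap
    p = PGSEParams(g=gmax, delta=delta, Delta=Delta, rise_time=rise,
                   grid=grid, gamma=gamma)
    return make_monopolar(p)
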