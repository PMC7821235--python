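"""Effective gradient waveforms and their derived encoding metrics.

A diffusion-encoding waveform on a spin-echo timeline is represented by its
*effective* gradient ``g(t)`` (the sign flip imparted by the refocusing
pulse is absorbed into the samples), from which all encoding metrics derive:

* the dephasing trajectory ``q(t) = gamma * int_0^t g dt'``,
* the b-tensor ``B = int_0^tau q q^T dt`` (trace = b-value),
* the motion-encoding moment vectors ``m_n = gamma * int_0^tau g t^n dt``,
* the concomitant-field (Maxwell) matrix ``int s(t) g_phys g_phys^T dt``,
* the encoding efficiency ``kappa = 4 b / (gamma^2 gmax^2 t_tot^3)``.

Samples are interpreted as a first-order hold (piecewise-linear gradient);
integrals use the trapezoid rule on the uniform grid except the Maxwell
matrix, which uses exact per-interval quadrature of products of linear
segments (see Notes in :func:`maxwell_matrix`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .grid import TimeGrid
from .units import GAMMA_H, b_from_si, maxwell_from_si

__all__ = [
    "EffectiveWaveform",
    "DephasingTrajectory",
    "BTensor",
    "MomentVector",
    "MaxwellMatrix",
    "EfficiencyReport",
    "compute_dephasing",
    "compute_btensor",
    "compute_moment",
    "maxwell_matrix",
    "maxwell_index",
    "efficiency",
    "rotate",
    "resample",
    "max_slew",
    "max_amplitude",
    "energy_per_axis",
]

#: Relative eigenvalue tolerance for b-tensor shape classification.
SHAPE_TOL = 1.0e-3


@dataclass
class EffectiveWaveform:
    """Per-axis effective gradient samples on a :class:`TimeGrid`.

    ``g`` has shape ``(grid.n_samples, 3)`` in T/m, effective convention
    (post-refocusing sign already flipped).  The gradient must vanish at the
    first and last sample and throughout the refocusing gap.
    """

    grid: TimeGrid
    g: np.ndarray
    gamma: float = GAMMA_H

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.shape != (self.grid.n_samples, 3):
            raise ValueError(
                f"waveform has {self.g.shape} samples, grid expects "
                f"({self.grid.n_samples}, 3)")
        gmax = np.abs(self.g).max() if self.g.size else 0.0
        tol = 1e-12 + 1e-9 * gmax
        if abs(self.g[0]).max() > tol or abs(self.g[-1]).max() > tol:
            raise ValueError("gradient must be zero at the first and last sample")
        if np.abs(self.g[self.grid.gap_slice]).max() > tol:
            raise ValueError("gradient must be zero during the refocusing gap")

    @property
    def physical(self) -> np.ndarray:
        """Physical-gradient view: ``sign_profile * g`` (T/m)."""
        return self.grid.sign_profile[:, None] * self.g


@dataclass
class DephasingTrajectory:
    """Cumulative dephasing ``q(t)`` (rad/m), shape (n_samples, 3)."""

    q: np.ndarray
    grid: TimeGrid

    @property
    def final(self) -> np.ndarray:
        """q at the end of encoding; equals the zeroth moment vector."""
        return self.q[-1]


@dataclass
class BTensor:
    """Symmetric 3x3 diffusion-encoding tensor (s/m^2 internally)."""

    matrix: np.ndarray

    @property
    def b(self) -> float:
        """b-value: trace of the tensor (s/m^2)."""
        return float(np.trace(self.matrix))

    @property
    def b_ms_um2(self) -> float:
        return b_from_si(self.b)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending."""
        return np.sort(np.linalg.eigvalsh(self.matrix))[::-1]

    @property
    def shape_label(self) -> str:
        """Classify the eigenvalue pattern.

        ``linear`` has one nonzero eigenvalue, ``planar`` two equal nonzero
        ones, ``spherical`` three equal ones; anything else is ``general``.
        Eigenvalues within ``SHAPE_TOL * b`` of each other (or of zero)
        count as equal (or zero).
        """
        b = self.b
        if b <= 0:
            return "undefined"
        lam = self.eigenvalues
        tol = SHAPE_TOL * b
        nonzero = lam > tol
        if nonzero.sum() == 1:
            return "linear"
        if nonzero.sum() == 2 and abs(lam[0] - lam[1]) < tol:
            return "planar"
        if nonzero.sum() == 3 and lam[0] - lam[2] < tol:
            return "spherical"
        return "general"


@dataclass
class MomentVector:
    """n-th order motion-encoding moment vector (rad s^n / m, gamma included)."""

    order: int
    value: np.ndarray

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.value))


@dataclass
class MaxwellMatrix:
    """Signed outer-product integral governing concomitant-field residuals.

    ``matrix`` is ``int s(t) g_phys g_phys^T dt`` in (T/m)^2 s; its Frobenius
    norm is the Maxwell index.  A waveform whose physical gradient after
    refocusing mirrors the one before has index zero, and phase errors from
    concomitant fields then cancel for any rotation of the waveform.
    """

    matrix: np.ndarray

    @property
    def index(self) -> float:
        """Frobenius norm, (T/m)^2 s."""
        return float(np.linalg.norm(self.matrix))

    @property
    def index_report(self) -> float:
        """Maxwell index in reporting units (mT/m)^2 ms."""
        return maxwell_from_si(self.index)


@dataclass
class EfficiencyReport:
    """Encoding efficiency and refocusing-interval diagnostics."""

    kappa: float
    b: float
    gmax: float
    ttot: float
    self_balanced: bool
    crusher_moment: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_dephasing(w: EffectiveWaveform) -> DephasingTrajectory:
    """Cumulative trapezoid integral of ``gamma * g`` (rad/m).

    ``q`` starts at zero and is constant across the refocusing gap; its final
    sample equals the zeroth moment vector.
    """
    q = w.gamma * cumulative_trapezoid(w.g, dx=w.grid.dt, axis=0, initial=0.0)
    return DephasingTrajectory(q=q, grid=w.grid)


def _trapezoid_weights(n: int, dt: float) -> np.ndarray:
    wts = np.full(n, dt)
    wts[0] = wts[-1] = dt / 2
    return wts


def compute_btensor(w: EffectiveWaveform) -> BTensor:
    """b-tensor ``B = int q q^T dt`` by the trapezoid rule (s/m^2)."""
    q = compute_dephasing(w).q
    wts = _trapezoid_weights(w.grid.n_samples, w.grid.dt)
    B = np.einsum("t,ti,tj->ij", wts, q, q)
    return BTensor(matrix=0.5 * (B + B.T))


def compute_moment(w: EffectiveWaveform, n: int, origin: float = 0.0) -> MomentVector:
    """Moment vector ``m_n = gamma * int g(t) (t - origin)^n dt``.

    The time origin defaults to the start of the encoding window.  Nulling is
    origin-invariant only when all lower orders are nulled as well (shifting
    the origin mixes ``m_n`` with lower-order moments through the binomial
    expansion of ``(t - origin)^n``).

    Notes
    -----
    On a uniform grid with zero gradient endpoints the trapezoid rule is
    exact for the piecewise-linear interpolant at ``n = 0`` and, given
    ``m_0 = 0``, the discretization errors telescope to zero for ``n = 1``
    and ``n = 2`` as well.
    """
    if n < 0:
        raise ValueError("moment order must be non-negative")
    t = w.grid.times - origin
    wts = _trapezoid_weights(w.grid.n_samples, w.grid.dt)
    m = w.gamma * ((wts * t**n)[:, None] * w.g).sum(axis=0)
    return MomentVector(order=n, value=m)


def maxwell_matrix(w: EffectiveWaveform) -> MaxwellMatrix:
    """Signed outer-product integral ``int s(t) g_phys g_phys^T dt``.

    With ``g_phys = s * g`` this equals ``int s g g^T dt`` in the effective
    convention.  Each inter-sample interval is integrated exactly for the
    linear interpolant (``int_0^1 [(1-x)a + x b][(1-x)c + x d] dx =
    ac/3 + (ad + bc)/6 + bd/3``): plain trapezoid would carry an
    ``O(dt^2 smax^2 tau)`` error comparable to typical index limits.
    """
    g = w.g
    s = w.grid.interval_signs
    a, b = g[:-1], g[1:]
    per = (np.einsum("ti,tj->tij", a, a) + np.einsum("ti,tj->tij", b, b)) / 3.0
    cross = (np.einsum("ti,tj->tij", a, b) + np.einsum("ti,tj->tij", b, a)) / 6.0
    M = w.grid.dt * np.einsum("t,tij->ij", s, per + cross)
    return MaxwellMatrix(matrix=0.5 * (M + M.T))


def maxwell_index(w: EffectiveWaveform) -> float:
    """Maxwell index (Frobenius norm of the Maxwell matrix), (T/m)^2 s."""
    return maxwell_matrix(w).index


#: |q| below this fraction of its maximum counts as balanced.
_BALANCE_TOL = 1.0e-6


def efficiency(w: EffectiveWaveform, gmax: float) -> EfficiencyReport:
    """Encoding efficiency ``kappa = 4 b / (gamma^2 gmax^2 t_tot^3)``.

    ``kappa`` is dimensionless, 1 for the (unrealizable) waveform at full
    amplitude and full dephasing for the whole duration; it is invariant
    under pure time-rescaling at fixed amplitude.  Also reports whether the
    waveform is self-balanced (|q| ~ 0 at every refocusing-gap sample) and
    the available crusher moment (max |q| over the gap).
    """
    if gmax <= 0:
        raise ValueError("gmax must be positive")
    ttot = w.grid.tau
    if ttot <= 0:
        raise ValueError("waveform has zero duration")
    traj = compute_dephasing(w)
    b = compute_btensor(w).b
    kappa = 4.0 * b / (w.gamma**2 * gmax**2 * ttot**3)
    qgap = np.linalg.norm(traj.q[w.grid.gap_slice], axis=1)
    qscale = np.linalg.norm(traj.q, axis=1).max()
    crusher = float(qgap.max()) if qgap.size else 0.0
    balanced = bool(crusher <= _BALANCE_TOL * max(qscale, 1.0))
    return EfficiencyReport(kappa=float(kappa), b=b, gmax=gmax, ttot=ttot,
                            self_balanced=balanced, crusher_moment=crusher)


def rotate(w: EffectiveWaveform, R: np.ndarray,
           gmax: float | None = None) -> EffectiveWaveform:
    """Rotate the waveform: samples mapped by ``R`` (proper rotation).

    Derived metrics transform exactly: ``B -> R B R^T``, ``m_n -> R m_n``.
    If ``gmax`` is given and any per-axis sample exceeds it after rotation
    (possible for max-norm-constrained waveforms), a warning is emitted.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-10) \
            or not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
        raise ValueError("R must be a proper rotation matrix")
    g_rot = w.g @ R.T
    if gmax is not None and np.abs(g_rot).max() > gmax * (1 + 1e-12):
        warnings.warn(
            "rotated waveform exceeds the per-axis amplitude bound "
            f"({np.abs(g_rot).max():.4g} > {gmax:.4g} T/m); max-norm "
            "waveforms are not rotation-safe", stacklevel=2)
    return EffectiveWaveform(grid=w.grid, g=g_rot, gamma=w.gamma)


def resample(w: EffectiveWaveform, dt: float) -> EffectiveWaveform:
    """Linearly resample onto a finer grid with spacing ``dt``.

    The new spacing is snapped so that every period spans a whole number of
    intervals; sample values are exact on the shared piecewise-linear
    interpolant.
    """
    k = max(1, round(w.grid.dt / dt))
    fine = TimeGrid(n_pre=w.grid.n_pre * k, n_post=w.grid.n_post * k,
                    n_gap=w.grid.n_gap * k, dt=w.grid.dt / k)
    g = np.stack([np.interp(fine.times, w.grid.times, w.g[:, a])
                  for a in range(3)], axis=1)
    return EffectiveWaveform(grid=fine, g=g, gamma=w.gamma)


def max_slew(w: EffectiveWaveform) -> float:
    """Maximum per-axis slew rate |dg/dt| (T/m/s), finite differences."""
    return float(np.abs(np.diff(w.g, axis=0)).max() / w.grid.dt)


def max_amplitude(w: EffectiveWaveform) -> float:
    """Maximum per-axis gradient amplitude (T/m)."""
    return float(np.abs(w.g).max())


def energy_per_axis(w: EffectiveWaveform) -> np.ndarray:
    """Energy proxy ``int g_a^2 dt`` per axis ((T/m)^2 s)."""
    wts = _trapezoid_weights(w.grid.n_samples, w.grid.dt)
    return (wts[:, None] * w.g**2).sum(axis=0)
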