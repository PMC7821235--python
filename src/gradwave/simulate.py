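"""Monte-Carlo spin-ensemble simulation of phase accrual under ballistic motion.

Each spin moves along a polynomial trajectory
``r(t) = sum_n f_n t^n / n! = r0 + v t + a t^2/2 + j t^3/6 + s t^4/24 + ...``
(ballistic regime: the motion does not change direction during encoding) and
accrues phase ``phi = gamma int g(t) . r(t) dt`` under the effective
gradient.  The ensemble signal is the average ``< exp(-i phi) >``: a
coherent (bulk) shift of positions yields a pure global phase with magnitude
one, whereas incoherent motion disperses the phases and attenuates the
magnitude.  Moment-nulled waveforms are insensitive to the corresponding
motion orders by construction.

The per-spin phase integral uses the trapezoid rule on the waveform grid
(resampled to at most 50 us); because ``r(t)`` is polynomial in ``t`` and
the rule is linear in the integrand, the quadrature factorizes over motion
orders, so the ensemble is evaluated without materializing per-spin
trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveform import EffectiveWaveform, resample

__all__ = ["MotionDistribution", "SpinEnsemble", "SimulatedSignal",
           "sample_ensemble", "simulate_signal", "attenuation_surface"]

#: Maximum integration step of the phase integral (s).
SIM_DT = 5.0e-5


@dataclass
class MotionDistribution:
    """Zero-mean normal per-order motion statistics.

    ``sigma[n]`` is the standard deviation of each Cartesian component of
    the order-``(n+1)`` motion coefficient: ``sigma[0]`` = velocity SD (m/s),
    ``sigma[1]`` = acceleration SD (m/s^2), ``sigma[2]`` = jerk SD (m/s^3),
    ``sigma[3]`` = snap SD (m/s^4), and so on.  Components are sampled
    independently, so each order's covariance tensor is ``sigma_n^2 * I``.
    """

    sigma: tuple = ()

    def __post_init__(self) -> None:
        self.sigma = tuple(float(s) for s in self.sigma)
        if any(s < 0 for s in self.sigma):
            raise ValueError("motion standard deviations must be non-negative")

    @property
    def max_order(self) -> int:
        """Highest polynomial order with nonzero SD (0 when static)."""
        return len(self.sigma)


@dataclass
class SpinEnsemble:
    """Per-spin polynomial-motion coefficients f_1..f_N (initial position 0).

    ``coefficients`` has shape (n_spins, max_order, 3); order index 0 is
    velocity.  The initial position is fixed at zero: it contributes no
    phase for any spin-echo (m0 = 0) waveform and a spatially uniform offset
    otherwise, neither of which affects the ensemble magnitude.
    """

    coefficients: np.ndarray
    seed: int

    @property
    def n_spins(self) -> int:
        return self.coefficients.shape[0]

    @property
    def max_order(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class SimulatedSignal:
    """Ensemble-averaged complex signal and Monte-Carlo uncertainty."""

    complex_mean: complex
    phase_sd: float
    mc_stderr: float

    @property
    def magnitude(self) -> float:
        return abs(self.complex_mean)


def sample_ensemble(dist: MotionDistribution, n: int,
                    seed: int = 0) -> SpinEnsemble:
    """Draw ``n`` spins with iid zero-mean normal motion coefficients."""
    if n < 1:
        raise ValueError("need at least one spin")
    rng = np.random.default_rng(seed)
    sig = np.array(dist.sigma, dtype=float)
    coeff = rng.standard_normal((n, len(sig), 3)) * sig[None, :, None]
    return SpinEnsemble(coefficients=coeff, seed=seed)


def _phase_weights(w: EffectiveWaveform, max_order: int) -> np.ndarray:
    """Trapezoid quadrature of ``gamma g(t) t^n / n!`` for n = 1..max_order.

    Returns shape (max_order, 3).  The time origin coincides with the moment
    integrals (start of the encoding window), so ``phi = sum_n w_n . f_n``
    with ``w_n`` the returned weights.
    """
    if w.grid.dt > SIM_DT:
        w = resample(w, SIM_DT)
    t = w.grid.times
    dt = w.grid.dt
    wts = np.full(t.size, dt)
    wts[0] = wts[-1] = dt / 2
    out = np.empty((max_order, 3))
    fact = 1.0
    for n in range(1, max_order + 1):
        fact *= n
        out[n - 1] = w.gamma * ((wts * t**n)[:, None] * w.g).sum(axis=0) / fact
    return out


def simulate_signal(w: EffectiveWaveform, e: SpinEnsemble) -> SimulatedSignal:
    """Ensemble mean of ``exp(-i phi)`` for the given waveform and spins.

    The Monte-Carlo standard error is estimated from the spread of the
    complex spin vectors projected on the direction of their mean.
    """
    if e.max_order:
        wn = _phase_weights(w, e.max_order)
        phi = np.einsum("snk,nk->s", e.coefficients, wn)
    else:
        phi = np.zeros(e.n_spins)
    z = np.exp(-1j * phi)
    mean = z.mean()
    if abs(mean) > 0:
        proj = (z * np.conj(mean) / abs(mean)).real
    else:
        proj = z.real
    stderr = proj.std(ddof=1) / np.sqrt(e.n_spins) if e.n_spins > 1 else 0.0
    return SimulatedSignal(complex_mean=complex(mean),
                           phase_sd=float(phi.std(ddof=0)),
                           mc_stderr=float(stderr))


def attenuation_surface(w: EffectiveWaveform, sigma_v_grid, sigma_a_grid,
                        n: int = 100_000, seed: int = 0):
    """Signal magnitude over a (velocity SD, acceleration SD) grid.

    Returns ``(magnitudes, stderrs)`` arrays of shape
    ``(len(sigma_v_grid), len(sigma_a_grid))``; each node is an independent
    ensemble drawn from a seed spawned deterministically from ``seed``.
    """
    sigma_v_grid = np.atleast_1d(np.asarray(sigma_v_grid, float))
    sigma_a_grid = np.atleast_1d(np.asarray(sigma_a_grid, float))
    if (sigma_v_grid < 0).any() or (sigma_a_grid < 0).any():
        raise ValueError("sigma grids must be non-negative")
    mags = np.empty((sigma_v_grid.size, sigma_a_grid.size))
    errs = np.empty_like(mags)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(mags.size)
    for idx, (i, j) in enumerate(np.ndindex(*mags.shape)):
        dist = MotionDistribution(sigma=(sigma_v_grid[i], sigma_a_grid[j]))
        ens = sample_ensemble(dist, n,
                              seed=int(children[idx].generate_state(1)[0]
                                       % (2**31)))
        sig = simulate_signal(w, ens)
        mags[i, j] = sig.magnitude
        errs[i, j] = sig.mc_stderr
    return mags, errs
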