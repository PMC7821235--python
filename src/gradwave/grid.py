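"""Discretized encoding timeline for spin-echo diffusion waveforms.

The timeline covers two encoding periods (duration ``delta1`` before and
``delta2`` after the refocusing pulse) separated by a forbidden gap of
duration ``gap`` during which the gradient is identically zero.  Samples are
uniform with spacing ``dt``; the sign profile maps the physical gradient to
the effective gradient (sign flipped after refocusing).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeGrid"]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid with a refocusing gap.

    Parameters
    ----------
    n_pre, n_post : int
        Number of sample intervals in the first / second encoding period.
    n_gap : int
        Number of sample intervals spanned by the refocusing gap.
    dt : float
        Sample spacing (s).

    Notes
    -----
    There are ``n_pre + n_gap + n_post + 1`` sample points, at times
    ``i * dt``.  The point at index ``n_pre`` is the last point of the first
    period (the gradient must already be zero there), and the point at index
    ``n_pre + n_gap`` the first of the second period.
    """

    n_pre: int
    n_post: int
    n_gap: int
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_pre < 1 or self.n_post < 1 or self.n_gap < 0:
            raise ValueError("need at least one interval per encoding period")

    @classmethod
    def from_timings(cls, delta1: float, gap: float, delta2: float,
                     dt: float) -> "TimeGrid":
        """Build a grid from period durations, rounding to whole intervals.

        Each duration is rounded to the nearest multiple of ``dt`` (at least
        one interval per encoding period), so the realized timings can differ
        from the request by up to ``dt / 2``.
        """
        n_pre = max(1, round(delta1 / dt))
        n_post = max(1, round(delta2 / dt))
        n_gap = max(0, round(gap / dt)) if gap > 0 else 0
        return cls(n_pre=n_pre, n_post=n_post, n_gap=n_gap, dt=dt)

    # -- derived timings ---------------------------------------------------
    @property
    def delta1(self) -> float:
        """Duration of the first encoding period (s)."""
        return self.n_pre * self.dt

    @property
    def delta2(self) -> float:
        """Duration of the second encoding period (s)."""
        return self.n_post * self.dt

    @property
    def gap(self) -> float:
        """Refocusing duration (s)."""
        return self.n_gap * self.dt

    @property
    def tau(self) -> float:
        """Total encoding time delta1 + gap + delta2 (s)."""
        return (self.n_pre + self.n_gap + self.n_post) * self.dt

    @property
    def n_samples(self) -> int:
        return self.n_pre + self.n_gap + self.n_post + 1

    @property
    def times(self) -> np.ndarray:
        """Sample times (s), origin at the start of the encoding window."""
        return np.arange(self.n_samples) * self.dt

    # -- structural index sets --------------------------------------------
    @property
    def gap_slice(self) -> slice:
        """Samples on which the gradient must vanish (gap incl. edges)."""
        return slice(self.n_pre, self.n_pre + self.n_gap + 1)

    @property
    def sign_profile(self) -> np.ndarray:
        """Per-sample +1 before the refocusing gap, -1 after.

        The flip is placed at the gap midpoint; samples inside the gap carry
        zero gradient so the choice does not affect any integral.
        """
        s = np.ones(self.n_samples)
        flip = self.n_pre + self.n_gap // 2
        s[flip + 1:] = -1.0
        return s

    @property
    def interval_signs(self) -> np.ndarray:
        """Sign of each of the ``n_samples - 1`` inter-sample intervals."""
        s = self.sign_profile
        # intervals inherit the sign of their left sample except the flip
        # interval, which lies inside the (zero-gradient) gap
        return np.where(s[:-1] + s[1:] >= 0, 1.0, -1.0)

    def free_indices(self) -> np.ndarray:
        """Indices of samples where the gradient is a free variable.

        Excludes the first and last sample and every gap sample (all pinned
        to zero).
        """
        idx = np.arange(self.n_samples)
        pinned = np.zeros(self.n_samples, dtype=bool)
        pinned[0] = pinned[-1] = True
        pinned[self.gap_slice] = True
        return idx[~pinned]
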