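"""Tensor-valued diffusion-and-motion signal model and diffusion-tensor fit.

For Gaussian diffusion with tensor ``D`` and independent zero-mean normal
ballistic motion with per-order covariance tensors ``F_n``, the encoded
signal is

    S = S0 * exp( -B:D - sum_n M_n:F_n / (2 (n!)^2) )

where ``B`` is the b-tensor and ``M_n = m_n (x) m_n`` the rank-1 motion
encoding tensor of order ``n``.  The ``1/(n!)^2`` factor follows from the
per-spin phase ``phi = sum_n m_n . f_n / n!`` and second-cumulant
truncation: the phase variance of order ``n`` is ``m_n^T F_n m_n / (n!)^2``
and ``S ~ exp(-<phi^2>/2)``.  With all moments nulled the model reduces to
the standard tensor-valued diffusion representation ``S0 exp(-B:D)``.

Units are SI throughout: ``B`` in s/m^2, ``D`` in m^2/s (1 um^2/ms =
1e-9 m^2/s), ``m_n`` in rad s^n/m, ``F_n`` in (m/s^n)^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .waveform import BTensor, MomentVector

__all__ = ["EncodingSpec", "TissueModel", "predict_signal", "fit_dtensor",
           "direction_set", "SingularDesignError"]


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the tensor-fit design matrix is rank deficient."""


@dataclass
class EncodingSpec:
    """One measurement's encoding: b-tensor plus moment vectors (orders >= 1)."""

    btensor: BTensor
    moments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(m.order < 1 for m in self.moments):
            raise ValueError("EncodingSpec moments start at order 1; the "
                             "zeroth moment is the spin-echo condition")

    @property
    def motion_tensors(self) -> dict:
        """Rank-1 tensors ``M_n = m_n (x) m_n`` keyed by order."""
        return {m.order: np.outer(m.value, m.value) for m in self.moments}


@dataclass
class TissueModel:
    """Gaussian diffusion tensor plus per-order motion covariances.

    ``Fn`` maps motion order to a 3x3 PSD covariance tensor; isotropic
    motion with component SD ``sigma_n`` corresponds to ``sigma_n^2 * I``.
    """

    D: np.ndarray
    Fn: dict = field(default_factory=dict)
    S0: float = 1.0

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (3, 3) or not np.allclose(self.D, self.D.T):
            raise ValueError("D must be a symmetric 3x3 tensor")
        if np.linalg.eigvalsh(self.D).min() < -1e-12 * max(
                1.0, abs(self.D).max()):
            raise ValueError("D must be positive semidefinite")
        for n, F in self.Fn.items():
            F = np.asarray(F, dtype=float)
            if F.shape != (3, 3) or np.linalg.eigvalsh(F).min() < -1e-12:
                raise ValueError(f"F_{n} must be a 3x3 PSD tensor")
            self.Fn[n] = F

    @property
    def md(self) -> float:
        """Mean diffusivity, trace(D)/3 (m^2/s)."""
        return float(np.trace(self.D)) / 3.0

    @classmethod
    def isotropic(cls, d: float, sigma: tuple = (), S0: float = 1.0):
        """Isotropic tissue: ``D = d I`` and ``F_n = sigma_n^2 I``."""
        Fn = {n + 1: s**2 * np.eye(3) for n, s in enumerate(sigma)}
        return cls(D=d * np.eye(3), Fn=Fn, S0=S0)


def predict_signal(enc: EncodingSpec, tissue: TissueModel) -> float:
    """Signal for one encoding under the diffusion-and-motion model."""
    from math import factorial

    expo = float(np.tensordot(enc.btensor.matrix, tissue.D))
    for n, M in enc.motion_tensors.items():
        F = tissue.Fn.get(n)
        if F is None:
            continue
        expo += float(np.tensordot(M, F)) / (2.0 * factorial(n)**2)
    return tissue.S0 * np.exp(-expo)


# ---------------------------------------------------------------------------
# diffusion-tensor fit
# ---------------------------------------------------------------------------

_COMP = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_COMP_NAMES = ["xx", "yy", "zz", "xy", "xz", "yz"]


def _design(encs) -> np.ndarray:
    X = np.empty((len(encs), 7))
    X[:, 0] = 1.0
    for r, enc in enumerate(encs):
        B = enc.btensor.matrix
        for c, (i, j) in enumerate(_COMP):
            X[:, 1 + c][r] = -(1.0 if i == j else 2.0) * B[i, j]
    return X


def fit_dtensor(signals, encs, weighted: bool = True) -> TissueModel:
    """Log-linear (weighted) least-squares diffusion-tensor fit.

    Regresses ``log(S)`` on the six unique b-tensor components plus an
    intercept; weights equal to the squared predicted signal correct the
    log-transform heteroscedasticity (one OLS pass to form predictions, one
    WLS pass; set ``weighted=False`` for plain OLS).  Motion terms are
    deliberately absent: applied to motion-corrupted data the fit inflates
    the apparent mean diffusivity, which is exactly its use as a
    signal-dropout detector.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 1 or len(signals) != len(encs):
        raise ValueError("need one scalar signal per encoding")
    if len(encs) < 7:
        raise ValueError("need at least 7 measurements for a tensor fit")
    if (signals <= 0).any():
        raise ValueError("signals must be positive for a log-linear fit")
    X = _design(encs)
    rank = np.linalg.matrix_rank(X, tol=1e-10 * abs(X).max())
    if rank < 7:
        _, _, vt = np.linalg.svd(X)
        null = vt[rank:]
        bad = [_COMP_NAMES[c] for c in range(6)
               if np.abs(null[:, 1 + c]).max() > 1e-6]
        raise SingularDesignError(
            "rank-deficient tensor design (rank "
            f"{rank}/7); unresolved components: {', '.join(bad) or 'S0'}")
    y = np.log(signals)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    if weighted:
        w = np.exp(X @ beta)          # predicted signal
        Xw = X * w[:, None]
        beta, *_ = np.linalg.lstsq(Xw, y * w, rcond=None)
    D = np.empty((3, 3))
    for c, (i, j) in enumerate(_COMP):
        D[i, j] = D[j, i] = beta[1 + c]
    return TissueModel(D=_psd_clip(D), S0=float(np.exp(beta[0])))


def _psd_clip(D: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues arising from numerics."""
    lam, V = np.linalg.eigh(D)
    floor = -1e-10 * max(1.0, abs(lam).max())
    if lam.min() < floor:
        return D                      # genuinely indefinite: leave visible
    return V @ np.diag(np.clip(lam, 0.0, None)) @ V.T


# ---------------------------------------------------------------------------
# direction sets from icosahedral geometry
# ---------------------------------------------------------------------------

def _icosahedron_vertices() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    base = [(0.0, 1.0, phi), (0.0, 1.0, -phi), (0.0, -1.0, phi),
            (0.0, -1.0, -phi)]
    pts = []
    for (x, y, z) in base:
        pts += [(x, y, z), (z, x, y), (y, z, x)]
    pts = np.array(pts)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _antipodal_unique(pts: np.ndarray) -> np.ndarray:
    out = []
    for p in pts:
        if not any(np.allclose(p, q, atol=1e-9)
                   or np.allclose(p, -q, atol=1e-9) for q in out):
            out.append(p)
    # canonical hemisphere: first significant component positive
    canon = []
    for p in out:
        k = np.argmax(np.abs(p) > 1e-9)
        canon.append(p if p[k] > 0 else -p)
    return np.array(canon)


def direction_set(n: int) -> np.ndarray:
    """Antipodally unique unit directions from icosahedral solids.

    ``n = 6``: icosahedron vertices (all pairwise angles equal);
    ``n = 15``: icosahedron edge midpoints (icosidodecahedron vertices);
    ``n = 30``: icosahedron edge trisection points (truncated-icosahedron
    vertices).  All three give full-rank rank-2 tensor designs.
    """
    verts = _icosahedron_vertices()
    if n == 6:
        return _antipodal_unique(verts)
    # edges: nearest-neighbor pairs at the icosahedral edge length
    d2 = ((verts[:, None] - verts[None]) ** 2).sum(-1)
    edge = np.isclose(d2, np.sort(np.unique(np.round(d2, 9)))[1])
    pairs = [(i, j) for i, j in combinations(range(len(verts)), 2)
             if edge[i, j]]
    if n == 15:
        mids = np.array([verts[i] + verts[j] for i, j in pairs])
    elif n == 30:
        mids = np.array([w1 * verts[i] + w2 * verts[j]
                         for i, j in pairs for w1, w2 in ((2, 1), (1, 2))])
    else:
        raise ValueError("supported direction counts are 6, 15 and 30")
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    out = _antipodal_unique(mids)
    if len(out) != n:
        raise AssertionError(f"expected {n} unique directions, got {len(out)}")
    return out
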