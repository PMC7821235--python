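"""Shared fixtures: analytic reference waveforms and cached optimizer runs.

The optimizer fixtures are session-scoped because constrained waveform
optimization is the expensive step; every test that needs a nulled waveform
shares the same deterministic (seeded) solve.
"""
import numpy as np
import pytest

from gradwave import (OptimizationSpec, PGSEParams, make_bipolar,
                      make_monopolar, maximize_b, minimize_duration)

PROTOCOL = dict(gmax=80e-3, smax=60.0, gap=8e-3)


@pytest.fixture(scope="session")
def mono():
    """Monopolar pair, 80 mT/m, 15 ms lobes, 10 us grid."""
    return make_monopolar(PGSEParams(g=0.08, delta=15e-3))


@pytest.fixture(scope="session")
def bipolar():
    """Velocity-compensated bipolar waveform (m1 = 0 by construction)."""
    return make_bipolar(PGSEParams(g=0.08, delta=10e-3))


@pytest.fixture(scope="session")
def m1_nulled():
    """Optimized linear-encoding waveform nulled through m1."""
    spec = OptimizationSpec(shape_target="linear", delta1=30e-3,
                            delta2=24e-3, null_orders=(0, 1),
                            thresholds={1: 1e-4}, n_points=80, restarts=2,
                            seed=3, **PROTOCOL)
    res = maximize_b(spec)
    assert res.converged
    return res.waveform


@pytest.fixture(scope="session")
def m2_nulled():
    """Optimized linear-encoding waveform nulled through m2, b = 2 ms/um^2."""
    from gradwave import EffectiveWaveform
    spec = OptimizationSpec(shape_target="linear", delta1=41e-3,
                            delta2=35e-3, null_orders=(0, 1, 2),
                            thresholds={1: 1e-4, 2: 1e-4},
                            maxwell_limit=100.0, n_points=100, restarts=2,
                            seed=3, **PROTOCOL)
    res = maximize_b(spec)
    assert res.converged and res.achieved_b >= 2.0e9
    s = np.sqrt(2.0e9 / res.achieved_b)
    w = res.waveform
    return EffectiveWaveform(grid=w.grid, g=s * w.g, gamma=w.gamma)


@pytest.fixture(scope="session")
def protocol_results():
    """Duration-minimized waveforms for the full study protocol.

    80 mT/m, 60 T/m/s, 8 ms refocusing, first period 6 ms longer than the
    second, moment thresholds L1 = L2 = 1e-4 rad s^n/m, Maxwell index
    <= 100 (mT/m)^2 ms, b = 2 ms/um^2, for all three b-tensor shapes.
    """
    out = {}
    for shape, d2_start in (("linear", 12e-3), ("planar", 18e-3),
                            ("spherical", 26e-3)):
        spec = OptimizationSpec(shape_target=shape, norm_mode="max",
                                delta1=d2_start + 6e-3, delta2=d2_start,
                                null_orders=(0, 1, 2),
                                thresholds={1: 1e-4, 2: 1e-4},
                                maxwell_limit=100.0, b_target=2.0e9,
                                n_points=100, restarts=5, seed=1, **PROTOCOL)
        out[shape] = minimize_duration(spec)
    return out
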