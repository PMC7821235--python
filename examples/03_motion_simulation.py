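"""Monte-Carlo demonstration of motion compensation.

Simulates 100 000 spins with normally distributed velocities under a
non-compensated monopolar pair and under a velocity-compensated bipolar
design, and compares the ensemble magnitude with the Gaussian prediction
exp(-|m1|^2 sigma_v^2 / 2).
"""
import numpy as np

from gradwave import (MotionDistribution, PGSEParams, compute_moment,
                      make_bipolar, make_monopolar, sample_ensemble,
                      simulate_signal)

mono = make_monopolar(PGSEParams(g=80e-3, delta=15e-3))
bip = make_bipolar(PGSEParams(g=80e-3, delta=10e-3))
m1 = compute_moment(mono, 1).magnitude

print("sigma_v [mm/s]   monopolar MC   Gaussian model   bipolar MC")
for sigma_v in (0.0, 0.05e-3, 0.1e-3, 0.2e-3):
    dist = MotionDistribution(sigma=(sigma_v,))
    ens = sample_ensemble(dist, 100_000, seed=7)
    s_mono = simulate_signal(mono, ens)
    s_bip = simulate_signal(bip, ens)
    model = np.exp(-(m1 * sigma_v) ** 2 / 2.0)
    print(f"{sigma_v * 1e3:12.2f}   {s_mono.magnitude:12.4f} "
          f"{model:16.4f} {s_bip.magnitude:12.4f}")

# Sub-millimetre-per-second velocity spreads already destroy the monopolar
# signal, exactly as the Gaussian characteristic function predicts, while
# the m1-nulled bipolar waveform stays at magnitude 1 -- the mechanism that
# rescues diffusion imaging in the beating heart.
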