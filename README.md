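# gradwave

Motion-compensated gradient waveform design for tensor-valued diffusion
encoding.

Diffusion MRI encodes the microscopic motion of water into signal
attenuation, but in moving organs — heart, liver, kidney — bulk and
incoherent tissue motion in the *ballistic* regime (direction constant over
the encoding time) dephases the spins far more strongly than diffusion does,
causing gross signal dropout. `gradwave` designs spin-echo gradient
waveforms that are simultaneously

* **tensor-valued**: the b-tensor `B = ∫ q(t) q(t)ᵀ dt`, with
  `q(t) = γ ∫₀ᵗ g dt′` the dephasing vector, can be made linear, planar or
  spherical in shape while its trace (the b-value) is maximized;
* **motion-compensated**: the moment vectors `mₙ = γ ∫ g(t) tⁿ dt` are
  constrained to `|mₙ| ≤ Lₙ` or nulled exactly; `m₁`-nulling removes all
  sensitivity to velocity, `m₂`-nulling to acceleration as well;
* **concomitant-field compensated**: the Maxwell index — the Frobenius norm
  of `∫ s(t) g(t) g(t)ᵀ dt` over the physical gradient with the refocusing
  sign `s(t)` — is bounded so that concomitant-gradient phase errors cancel
  for arbitrary rotations of the waveform;
* **hardware-feasible**: per-axis (max-norm) or Euclidean (L2-norm)
  amplitude limits, slew-rate limits, asymmetric encoding periods around a
  refocusing gap, optional per-axis energy bounds.

The optimizer treats the free gradient samples as decision variables,
eliminates nulled moments exactly in a null-space parametrization and
solves the remaining smooth problem by multi-start SQP. An outer search
minimizes the encoding duration that reaches a requested b-value. A
Monte-Carlo spin simulator (polynomial trajectories
`r(t) = Σ fₙ tⁿ/n!`) and the generalized signal representation

    S = S₀ · exp( −B:D − Σₙ Mₙ:Fₙ / (2 (n!)²) ),   Mₙ = mₙ ⊗ mₙ,

validate the designs, and a b-tensor-aware diffusion-tensor fit turns mean
diffusivity (MD = Tr D / 3) into a detector of motion-induced dropout.

## Worked example

```python
from gradwave import OptimizationSpec, maximize_b, describe

spec = OptimizationSpec(
    shape_target="linear", gmax=80e-3, smax=60.0,
    delta1=24e-3, delta2=18e-3, gap=8e-3,
    null_orders=(0, 1), thresholds={1: 1e-4},
    maxwell_limit=100.0, n_points=80, restarts=3, seed=1)
result = maximize_b(spec)
report = describe(result.waveform, gmax=spec.gmax)
print(result.achieved_b / 1e9, report["moment_magnitudes"]["m1"])
```

Running `examples/01_design_motion_compensated_waveform.py` prints

```
converged:        True
b-value:          0.502 ms/um^2
b-tensor shape:   linear
|m1| residual:    1.22e-12 rad s/m
Maxwell index:    100.0 (mT/m)^2 ms
efficiency kappa: 0.035
```

i.e. on a 24 + 8 + 18 ms spin-echo timeline the optimizer reaches
b = 0.5 ms/µm² with the first moment at numerical zero — roughly ten orders
of magnitude below the ~7·10³ rad s/m that a comparable non-compensated
monopolar pair carries (`examples/02_reference_waveforms.py`), which is the
difference between a usable and a destroyed signal in the beating heart
(`examples/03_motion_simulation.py`). The efficiency factor
`κ = 4b / (γ² g²max t³tot)` reports the attained fraction of the
theoretical maximum diffusion weighting.

The other examples cover the analytic monopolar/bipolar references, the
Monte-Carlo attenuation surfaces and the MD-based dropout detector. The
same functionality is scriptable from the shell:

```bash
gradwave optimize --shape ste --null-orders 0,1,2 -b 2.0 --maxwell 100 \
    --seed 1 -o ste_m2.gwf
gradwave describe ste_m2.gwf
gradwave simulate --wav ste_m2.gwf --sigma-v 0,1,10 -n 100000 --seed 1
```

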