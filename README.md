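# fgpgm — ODE parameter inference with partially observed states

`fgpgm` estimates the time-independent parameters θ of a nonlinear ODE
system ẋ(t) = f(x(t), θ) from noisy time series in which only *some* state
variables are measured. It is aimed at systems-biology-style problems
(predator–prey dynamics, spiking-neuron models, signalling pathways) where
instrumenting every species is impossible but the model structure is known.

## Method

The estimator combines **Gaussian-process gradient matching** with a
deterministic **trajectory-matching refinement**:

1. **GP fit.** Each measured state x_k gets an independent GP prior with
   kernel k_φ; hyperparameters φ and the noise sd σ are fitted by maximizing
   the marginal likelihood of the observations y_k.
2. **Gradient-matching MCMC.** Because a GP is closed under
   differentiation, the state derivatives on the grid satisfy
   ẋ_k | x_k ~ N(D_k(x_k − μ_k), A_k). A one-chain componentwise Metropolis
   sampler draws states and parameters from

   ρ(x_M, θ | y) ∝ ρ(θ) · N(x_M | 0, C_φ) · N(y | x_M, σ²I) ·
   N(f_M(x_M, x̃_L, θ) | D x_M, A + γ²I),

   where γ is a model-mismatch standard deviation and x̃_L is the latent
   (unmeasured) trajectory. Unmeasured states are handled by one of three
   interchangeable strategies: **full integration** of the system at each
   proposed θ, **partial integration** (forward Euler of the latent
   subsystem with the measured states interpolated from the data), or **GP
   sampling** (latent values are sampled alongside the measured ones, scored
   by a latent gradient-matching density).
3. **Refinement.** The posterior-mean θ seeds a deterministic least-squares
   descent on Σᵢ |x_M(tᵢ; θ) − y(tᵢ)|². Starting from the sampler's estimate
   is what keeps this local search out of the spurious minima that trap a
   cold-started fit.

A local sensitivity module computes the normalized indices
S_ij = ‖∂x_i/∂θ_j‖_{L2} / ‖x_i‖_{L2} at θ*, which predict which parameters a
given observation scheme can pin down.

Benchmarks built in: Lotka–Volterra, FitzHugh–Nagumo, a five-species
protein-transduction pathway, and an indirect-observation example
(y = e^{x1} measured, augmented to a three-state system). User systems can
be defined in config files with a small arithmetic expression grammar.

## Worked example

Sensitivities of the Lotka–Volterra states to the parameters at
θ* = (2, 1, 4, 1):

```bash
$ fgpgm sensitivity --system lotka_volterra
              x1        x2
theta1      0.20      0.61
theta2      0.52      1.13
theta3      0.40      0.33
theta4      1.26      0.98
```

θ4 is the best-identified parameter from either state; θ1 and θ3 are the
hardest. Inference on the FitzHugh–Nagumo neuron with only x1 measured
(50 points on [0, 10], noise sd 0.1, x2 latent):

```python
import numpy as np
from fgpgm import experiments

run = experiments.fhn_strategy(seed=3, strategy="full_integration", refine=True)
print("FGPGM estimate:   ", np.round(run.theta_fgpgm, 3))
print("after refinement: ", np.round(run.theta_refined, 3))
print("true parameters:  ", run.theta_true)
```

```
FGPGM estimate:    [0.304 0.311 2.816]
after refinement:  [0.21  0.226 2.989]
true parameters:   [0.2 0.2 3. ]
```

The sampler's estimate is already in the right basin; the least-squares
polish then closes most of the remaining gap. A YAML-driven version of the
same workflow (data synthesis or CSV input, GP fit, MCMC, refinement,
error metrics) is available as `fgpgm pipeline -c run.yaml`; see
`fgpgm --help` for the other subcommands (`simulate`, `fit-gp`, `infer`,
`refine`, `sensitivity`).

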