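# sgmfc — spectral graph model of band-specific functional connectivity

`sgmfc` predicts frequency-band-specific functional connectivity (FC) of
the brain from its structural connectome, and infers the model's
biophysical parameters from observed FC with simulation-based Bayesian
inference. It is aimed at researchers studying the structure–function
relationship in MEG/EEG: given a tract-weight matrix `C` and inter-region
distances, the package produces closed-form coherence-like FC matrices in
the canonical delta/theta/alpha/beta bands, fits them to empirical
coherence FC, and benchmarks the result against graph-diffusion
eigen-mapping, a coupled Wilson–Cowan network, and the raw SC itself.

## The model

Connections carry conduction delays `τ_ij = d_ij / v`, giving the
frequency-dependent **complex Laplacian**

    ℒ(ω) = I − α C*(ω),    c*_ij(ω) = c_ij exp(−j ω d_ij / v),

where `C` is the sqrt-degree-normalized weight matrix. With
`ℒ(ω) = U(ω) Λ(ω) U^H(ω)` and the gamma-shaped neural response
`F_g(ω) = 1/(1 + jωτ_g)²`, white-noise-driven activity has the
cross-spectral density

    F̂(ω) = Σ_k u_k u_k^H / |jω + τ_g⁻¹ λ_k(ω) F_g(ω)|² ,

and the band FC is the band-summed CSD normalized by its diagonal
(`Δ^{-1/2} Σ_ω F̂(ω) Δ^{-1/2}`, element-wise modulus, zero diagonal) —
directly comparable to magnitude coherence. Normalization cancels the
input variance and all local (mesoscopic) response terms, so the FC
depends on just three global parameters:

| parameter | meaning                              | admissible range |
|-----------|--------------------------------------|------------------|
| `τ_g`     | long-range neural time constant      | 0.005 – 0.03 s   |
| `v`       | axonal conduction speed              | 5 – 20 m/s       |
| `α`       | global coupling constant             | 0.1 – 1          |

Inference maps the parameters to an unconstrained space with a logit
transform, centres a Gaussian prior on a dual-annealing point fit, and
runs sequential neural posterior estimation (three rounds of 1000
simulations by default), returning a full posterior with the Jacobian
correction back to the bounded space. A single parameter set can be
fitted to all four bands jointly by stacking the band FC matrices.

## Worked example

```python
import numpy as np
from sgmfc import (SyntheticSpec, generate_connectome, preprocess_sc,
                   generate_observation, SGMParams, DEFAULT_BANDS,
                   train_posterior)

sc = preprocess_sc(generate_connectome(SyntheticSpec(n_regions=16, seed=0)))
truth = SGMParams(tau_g=0.015, v=12.0, alpha=0.5)
obs = generate_observation(sc, truth, DEFAULT_BANDS, noise_sd=0.05, seed=100)

post = train_posterior(obs.shared, sc, rounds=2, M=300, noise_sd=0.05, seed=0)
print(np.round(post.mean_theta.as_array(), 4))
print({k: round(v["q95"] - v["q05"], 4) for k, v in post.summary().items()})
```

prints

```
[ 0.0144 12.8129  0.5827]
{'tau_g': 0.003, 'v': 2.3947, 'alpha': 0.2011}
```

— the posterior mean recovers the generating parameters
`(0.015, 12.0, 0.5)` to within 4–17% per coordinate, and the second line
shows each parameter's 90% credible-interval width. The same fit is
available from the shell:

```
sgmfc make-synthetic --out demo --n-regions 16 --seed 0 --noise-sd 0.05
sgmfc fit --sc-dir demo/sc_preprocessed --fc demo/fc_delta.csv \
          --fc demo/fc_theta.csv --fc demo/fc_alpha.csv --fc demo/fc_beta.csv \
          --shared --rounds 2 --sims-per-round 300 --noise-sd 0.05 \
          --seed 0 --out demo/fit
```

Other subcommands: `predict` (model FC for given parameters),
`benchmark --method nmm|eigenmap|direct`, and `evaluate` (Pearson/Lin/MSE
with shuffle- or spin-null standardization).

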