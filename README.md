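# timweb

Trophic interaction modifications (TIMs) in community dynamics models:
model construction and simulation, a full suite of TIM-strength metrics,
equilibrium/Jacobian/net-effects analysis, TIM-parameter sweeps, and
synthetic multi-level functional-response experiments with parameter
fitting.

## The problem

Consumer–resource interactions in food webs are frequently altered by
third species: a predator's presence makes a herbivore forage less, one
host's density changes a shared parasitoid's attack on another, and so
on.  `timweb` represents such a **trophic interaction modification** as a
density-dependent multiplier on one functional-response parameter.  For a
link between resource *i* and consumer *j* modified by species *k*, the
attack rate *a* (or handling time *h*, or an interference coefficient)
becomes

```
a_eff = a · f(c_ijk, K)
```

where *K* is the modifier's density and *c_ijk* is the signed TIM
strength.  Four modification forms are shipped: `exponential`
(`exp(c·K)`), `linear_clipped` (`max(0, 1 + c·K)`), `hyperbolic`
(saturating: `1 + c·K` for amplification, `1/(1 + |c|·K)` for
attenuation) and `sigmoid` (thresholded).  Every form reduces to exactly
1 at `c = 0`, so a zero-strength TIM leaves the dynamics bit-for-bit
unchanged.  A TIM may be *dynamic* (the modifier is a state variable with
full feedback) or *forced* (a cue held at fixed density, as in
disabled-predator experiments).

Because "how strong is this modification?" has no single answer, the
package computes a ladder of metrics that fold in increasing amounts of
system context, for any TIM at any system state:

| metric | meaning |
| --- | --- |
| modification parameter | the strength `c_ijk` itself |
| modification term | `f(c_ijk, K)` at the state |
| flux change | unmodified/modified biomass flux, as ratio `Δrel` and difference `Δabs` |
| change in B_CR | resource equilibrium density with the TIM over without (`I*/I*_{c=0}`) |
| CV of modification | sd/mean of the term along a trajectory (non-stationary systems) |
| Jacobian elements | `(∂İ/∂K, ∂J̇/∂K)` — the pairwise (TMII) framing |
| Jacobian sensitivity | `(∂A_ij/∂K, ∂A_ji/∂K)` — effect on the *direct* interaction |
| net-effects sensitivity | `(∂(−A⁻¹)_ij/∂K, ∂(−A⁻¹)_ji/∂K)` — direct plus indirect routes |

All derivative metrics are direct partials (no re-equilibration) and are
available both symbolically (sympy) and by finite differences, each
serving as an oracle for the other.  See `docs/methods.md` for the model
definitions, numerical choices, and limitations.

## Worked example

```python
import numpy as np
from timweb import build_demo, find_equilibrium, compute_all_metrics

model = build_demo("chain_nonlinear")   # plant-herbivore-predator, Holling II
eq = find_equilibrium(model, np.ones(3))
print(dict(zip(model.species_order, eq.state.densities.round(4))), eq.stability)

report = compute_all_metrics(model, "T1", at="equilibrium")
```

prints

```
{'P': 6.9897, 'H': 0.4571, 'C': 0.7882} stable
modification_parameter     -0.1
modification_term          0.9242
flux_ratio                 1.0578
flux_difference            0.0369
bcr_change                 1.006
tmii_i                     0.046
tmii_j                     -0.283
jacobian_sensitivity_i     0.1007
jacobian_sensitivity_j     -0.0015
net_sensitivity_i          -0.007
net_sensitivity_j          0.0
```

The demo's TIM is the predator (`C`) depressing the plant–herbivore
attack rate with strength `c = -0.1`.  At the equilibrium the
modification term is 0.92 (an 8% weakening), so the unmodified/modified
flux ratio sits just above 1 and the plant's equilibrium gains 0.6%
relative to the TIM-free system (`bcr_change = 1.006`).  The TMII pair
shows the modifier's direct effect on each interactor's growth rate; the
Jacobian-sensitivity pair shows how the predator's density reshapes the
direct plant–herbivore interaction terms; and the net-effects pair folds
in indirect (density-mediated) pathways as well.

The same analyses are scriptable from a shell:

```
timweb demo --name chain_linear --out out/
timweb sweep --demo chain_nonlinear --tim T1 --from -1 --to 1 --steps 41 --out out/
timweb scan-stabilize --out out/
timweb gen-experiment --noise-cv 0.05 --out out/ && timweb fit --data out/experiment.csv --out out/
```

Every command writes CSV/JSON outputs plus a `run_log.json` with the
seed, tolerances, versions and a model content hash, so runs are exactly
reproducible.

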