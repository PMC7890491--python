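# dspom

Dynamic stochastic patch occupancy modelling for wetlandscapes — mosaics of
geographically isolated wetlands whose habitat value rises and falls with the
weather.

## The problem

Classical metapopulation theory treats habitat patches as static: a species
with colonization rate *c*, extinction rate *e* and dispersal distance *D*
persists on a landscape whenever the **metapopulation capacity** λ_max — the
leading eigenvalue of the landscape matrix

    m_ij = exp(−d_ij / D) · S_i · S_j   (i ≠ j),   m_ii = 0

— exceeds *e/c*. In wetland-dominated landscapes this picture is wrong on the
time scale that matters: patch suitability S_i(t) (wetted area, or a depth
zone of it) and the perimeter-to-perimeter gap distances d_ij(t) fluctuate
daily with rainfall and evapotranspiration. `dspom` couples

1. a **stochastic forcing** generator (marked-Poisson daily rainfall with mean
   storm depth α and frequency λ; Thornthwaite or constant PET),
2. a **per-wetland water balance** on power-law bathymetry
   A(h) = A_max·(h/h_max)^(2/p), with rainfall captured over the wetland and
   its contributing area, ET and groundwater leakage over the wetted area,
3. a daily **colonization/extinction Markov chain** (an SIS-type process on a
   time-varying weighted network): unoccupied patches are colonized with
   probability 1 − exp(−C_i Δt), where
   C_i(t) = c·Σ_{j≠i} exp(−d_ij(t)/D)·S_j(t)·p_j(t), and occupied patches
   blink out with probability 1 − exp(−E_i Δt), E_i(t) = e / S_i(t),
4. the time-resolved capacity λ_max(t) and the emergent **dispersal network**
   of occupied patches (degree, betweenness, weighted diameter L(t), and the
   network length duration curve — the exceedance curve of L over time).

A static variant (`run_static_spom`) freezes suitability and gaps at their
time means, which is the classical model; comparing the two isolates what the
temporal dimension adds. A niche **metacommunity** layer runs independent
chains for species tied to the shallow (< 30 cm), intermediate (30–80 cm) and
deep (> 80 cm) water zones of each wetland.

Intended users: spatial ecologists and ecohydrologists studying species
persistence in ephemeral patchy habitats, and anyone needing a transparent,
fully seeded SPOM engine on a dynamic landscape.

## Worked example

```python
import numpy as np
from dspom import *
from dspom.geometry import centre_distances, gap_matrix, nnd

landscape = generate_archetype("dense", extent=(1400.0, 1400.0), seed=1)
forcing = generate_forcing(alpha=0.90, lambda_freq=0.20, T=1095, pet=0.50, seed=2)
hydro = simulate_hydrology(landscape, forcing, HydroParams(k_leak=0.1))

D = 1.5 * nnd(gap_matrix(centre_distances(landscape), landscape.a_max))
traits = SpeciesTraits(e=0.01, c=0.05, D=D)

dynamic, capacity = run_dspom(landscape, hydro, traits, n_realizations=100, seed=3)
static, _ = run_static_spom(landscape, hydro, traits, n_realizations=100, seed=3)

stats = landscape_stats(landscape, hydro)
print(f"patches: {len(landscape)}, dispersal distance D = {D:.1f} m")
print(f"mean A*(t)          = {stats['A_star'].mean():.3f}")
print(f"mean lambda_max(t)  = {capacity.lambda_max.mean():.3f}  (threshold e/c = {traits.e/traits.c:.3f})")
print(f"mean occupancy      = {dynamic.omega.mean():.3f} (dynamic) vs {static.omega.mean():.3f} (static)")
print(f"surviving fraction  = {dynamic.f_S:.2f}")

net = network_series(landscape, hydro, dynamic.p[0], traits.D)
cv = net["L"].std() / net["L"].mean()
print(f"network length CV   = {cv:.2f}; median L = {np.median(net['L']):.0f} m")
```

Output:

```
patches: 59, dispersal distance D = 26.5 m
mean A*(t)          = 0.884
mean lambda_max(t)  = 23.528  (threshold e/c = 0.200)
mean occupancy      = 0.503 (dynamic) vs 0.508 (static)
surviving fraction  = 1.00
network length CV   = 0.56; median L = 31 m
```

Reading it: a dense synthetic wetlandscape (59 patches in ~2 km²) stays on
average near 88 % of its full-pool area under this forcing; the capacity sits
two orders of magnitude above the persistence threshold, so every one of 100
Monte-Carlo metapopulations survives the 3-year run. The dynamic and static
engines agree on the *mean* occupancy (≈0.50) — what the static model misses
is the variability: occupancy and the dispersal-corridor length L(t) swing
with every storm and recession (CV ≈ 0.56 here), which is exactly the signal
the duration curve `nldc(...)` summarises.

## Command line

`dspom run config.yaml --out outdir` executes a YAML-configured experiment
(`dspom`, `static`, `sensitivity-grid` over an e×c lattice, or
`metacommunity`) and writes delimited tables plus a `manifest.yaml` from
which any output is regenerable. `dspom validate config.yaml` checks a
config and lists defaulted fields; `dspom generate-landscape` and
`dspom generate-forcing` write synthetic inputs.

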