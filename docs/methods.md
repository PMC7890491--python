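# Methods

## Model overview

`dspom` simulates a focal species (or several non-interacting ones) on a
landscape of depressional wetland patches whose suitability and spacing are
driven by daily hydroclimatic forcing. The chain of models is strictly
feed-forward: forcing → per-wetland water balance → patch suitabilities and
gap distances → (a) occupancy Markov chain, (b) metapopulation capacity,
(c) dispersal-network topology. Nothing feeds back from the biology to the
hydrology.

## Wetland geometry

Each patch is an equivalent circle. Real wetland outlines are irregular, but
every quantity the model consumes — wetted area, perimeter-to-perimeter gap,
depth-zone areas — is well defined for a circle of the same area, and the
circular approximation removes any GIS dependency. Bathymetry is a power law

    A(h) = A_max · min(1, h/h_max)^(2/p),
    V(h) = A_max · h_max · (h/h_max)^(2/p+1) / (2/p + 1),

so `p = 2` is a cone-like basin (area linear in stage), small `p` a
flat-bottomed pan, large `p` a plate-like depression. `V` is the exact
antiderivative of `A`, so dV/dh = A(h) and the pair inverts in closed form.

Two synthetic archetypes set the generator defaults:

| parameter | dense (pothole-like) | sparse (playa-like) |
|---|---|---|
| density | 30 km⁻² | 1 km⁻² |
| A_max | lognormal, mean 1.27·10⁴ m², CV 1.5 | lognormal, mean 5·10⁴ m², CV 0.3 |
| h_max | lognormal, mean 1.2 m, CV 0.4 | lognormal, mean 1.0 m, CV 0.2 |
| p | uniform [1, 4] | uniform [1.8, 2.2] |
| ca_ratio | 2.0 | 3.0 |
| min centre separation | 30 m | 300 m |

Densities and total-area scales follow the contrast between glacially formed
prairie-pothole terrain (dense, heterogeneous, ~0.38 km² of wetland per km²)
and wind-carved playa terrain (sparse, homogeneous, ~0.05 km² per km²). The
remaining distributions are not published anywhere as per-wetland tables;
the values above are field-plausible choices (pothole depths of order a
metre with strong bathymetric diversity from ice scouring; playas shallow
and mutually similar; upland contributing areas a small multiple of the
wetland area) and every one is configurable per call. Centres follow a
hard-core (minimum-separation) point process via bounded rejection sampling.

## Forcing

Rainfall is a marked Poisson process aggregated daily: storm counts per day
are Poisson(λ), storm depths exponential with mean α cm, so the daily total
is Gamma-distributed given the count, with mean αλ and variance 2α²λ —
closed forms the tests and the acceptance script check at T = 10⁵ days.
Exponential marks are the convention of the ecohydrological stochastic-
forcing lineage this model sits in. Counts-per-day (rather than a wet/dry
Bernoulli) keep λ > 1 d⁻¹ meaningful.

PET is either a fixed rate (default 0.50 cm d⁻¹, the value used throughout
the sensitivity analyses) or Thornthwaite's monthly method: heat index
I = Σ(T_m/5)^1.514 over months with T_m > 0, PET_m = 16(L_m/12)(N_m/30)
(10T_m/I)^a mm with the standard cubic a(I), day length from the
sunset-hour-angle formula at mid-month, monthly totals spread uniformly over
the month's days. An all-freezing year yields zero PET, not an error.

## Water balance

Daily, per wetland, with volume as the state variable:

    V' = V + rain·(A(h) + ca_ratio·A_max) − (pet_coeff·PET + k_leak)·A(h)

(depths converted cm → m). V′ is floored at zero (the unmet part of the
demanded losses is tracked as a deficit) and capped at V(h_max) (the excess
is spill, which leaves the system — wetlands are geographically isolated, no
inter-wetland routing). Carrying volume rather than stage makes the balance
a pure sum of the recorded fluxes:

    V(T) − V(0) = Σ(inflow − ET − leak − spill + deficit)

closes to ~10⁻¹⁶ relative over a 10-year, 50-wetland run (tested at 10⁻⁹).
Groundwater exchange is linear in wetted area (`k_leak`, cm d⁻¹, positive =
loss); a stage-dependent law can be emulated through `pet_coeff`/`k_leak`
configuration but is not built in. Initial condition defaults to full pool
(configurable as a fraction or per-wetland array); runs meant to start from
climatic equilibrium should discard a spin-up window of a few recession
time scales.

Depth zones: the area with local depth exceeding d equals A(h − d), so

    A_deep = A(h − 0.8)·[h > 0.8],
    A_int  = A(h − 0.3)·[h > 0.3] − A_deep,
    A_shallow = A(h) − A(h − 0.3)·[h > 0.3].

The three telescope to A(h) exactly (a few ulp in floating point). "Deep"
means strictly greater than 80 cm: at h = 0.8 m the deep zone is empty.

## Gap distances and landscape statistics

d_ij(t) = max(0, ‖x_i − x_j‖ − r_i(t) − r_j(t)) with r = √(A/π). Dry patches
keep their coordinates and enter with r = 0; suitability zero removes them
from the dynamics, so all matrices keep a constant shape over time. Computed
as centre-distance matrix minus the symmetric radius-sum matrix, which keeps
the result exactly symmetric in floating point.

Per-day statistics: A* = ΣA_i(t)/ΣA_max,i; NND = mean over wet patches of
the minimum gap to another wet patch; r_CV = CV of wet-patch areas over CV
of their pairwise gaps (cross-sectional, at fixed t). NND and r_CV are
reported as missing (NaN), never zero, on days with fewer than two wet
patches. Whether NND averages over all patches or wet ones only is a
genuine ambiguity; wet-only is the default and the alternative is a flag.

## Occupancy chain

Synchronous discrete-time update with Δt = 1 day (matching the forcing):
colonization and extinction probabilities 1 − exp(−rate·Δt) are both
evaluated from the state at time t, then one uniform draw per patch per
realization decides the transition. The update is vectorised over
realizations; identical seeds give identical ensembles. Suitability is
dimensionless: S_i(t) = A_i(t)/Ā where Ā is the landscape mean full-pool
area (configurable reference). The trait coefficients e and c are therefore
calibrated against order-one suitabilities; all threshold properties are
covariant under a change of reference. Initial occupancy defaults to "all
suitable patches occupied"; a Bernoulli fraction or explicit vector is
accepted. A patch with S = 0 cannot be colonised and, if occupied, empties
with probability 1 at the next step; the all-empty state is absorbing.

λ_max(t) is the leading eigenvalue (numpy `eigvalsh`) of the day's landscape
matrix — deterministic given the hydrology, unaffected by chain
stochasticity. The static engine freezes S at its time mean and the gaps at
those of the time-mean areas, then runs the *same* chain code consuming the
*same* random-number stream, so under time-constant hydrology the static
and dynamic trajectories are bit-identical — a structural degeneracy the
tests assert rather than a numerical coincidence.

Survival (f_S) is defined as: at least one occupied patch on the final
simulated day, the fraction taken over realizations.

A caveat that matters for interpreting the persistence threshold: the
criterion λ_max > e/c is the linearised continuous-time result. The daily
chain recovers it only when rates are small relative to 1/Δt — with rates of
order one per day the extinction probability saturates at 1 while a single
occupied patch can still seed several colonizations, and the discrete chain
persists far above the nominal threshold. The threshold-recovery test
therefore uses c = 0.01 d⁻¹ and a homogeneous landscape (area CV 0.2, 20
comparable patches), the regime the theory addresses; strongly heterogeneous
landscapes concentrate capacity in a few patches and show quasi-stationary
extinction well below threshold, which is a real effect, not a bug.

## Dispersal networks

Nodes are the occupied patches of one realization (realization 0 by default
in the pipeline drivers; any (T, n) occupancy array is accepted). An edge
joins two nodes when gap ≤ D — the boundary case is connected — and carries
the gap as weight. Degree and betweenness come from networkx (betweenness
unweighted: hop-count shortest paths, endpoints excluded, pair counts split
among ties); the network length L is the gap-weighted shortest-path diameter
via scipy's sparse graph routines. For a fragmented graph L is the maximum
over components of their diameters, so it tracks the longest surviving
corridor through fragmentation episodes; a largest-component variant is
selectable. The NLDC sorts L(t) descending and assigns the k-th largest the
Weibull plotting position k/(n+1), a valid empirical survival curve.

## Metacommunity

Three species, one per depth zone, fully independent chains: suitability is
the zone-area series divided by the same landscape reference area, so a
common (e, c) is comparable across zones. Per-species RNG streams are seeded
`[master_seed, zone_index]` with a fixed zone → index map, making results
independent of species ordering. Extinction day is the first day with zero
occupied patches, reported per realization with the ensemble median.

## Numerical choices and problem sizes

- Eigenvalues: `eigvalsh` on the dense symmetric matrix; inputs checked
  symmetric to 10⁻⁸ relative. Capacity of an empty landscape is 0.
- Event probabilities use `-expm1(-x)` for accuracy at small rates.
- Mass-balance closure asserted at 10⁻⁹ relative (observed ~10⁻¹⁶).
- Default experiment sizes in tests and the acceptance script — 20-patch
  threshold runs over 10⁴ days, a 59-patch dense landscape over 3 years
  with 20–100 realizations, 50 wetlands over 10 years for the water
  balance — are the package's chosen demonstration scales: large enough for
  the asymptotic properties under test, small enough to run interactively.

## What the synthetic generator does and does not emulate

It reproduces landscape-level summary statistics (density, total area,
heterogeneity contrast) of the two archetypes, not any real landscape's
spatial pattern: real wetlands cluster along geomorphic features, their
areas correlate with their depths and neighbours, and real forcing has
seasonality and interannual persistence that a homogeneous marked-Poisson
process lacks. Passing tests therefore demonstrate the model's internal
consistency and its qualitative mechanisms (threshold recovery, dynamic
variability exceeding static, niche-zone extinction under drying), not
quantitative predictions for any named place. Headline numbers published
for real case-study landscapes depend on inventory polygons and station
records that are not packaged and are out of scope here.

## Known limitations

- No upland-matrix resistance or anisotropic dispersal; the kernel is
  isotropic exp(−d/D) always.
- No species interactions, rescue effects, or trait evolution.
- No inter-wetland surface connectivity (fill-and-spill), groundwater head
  dynamics, or snow.
- Betweenness is hop-count based; a gap-weighted variant would rank
  stepping-stones differently in strongly heterogeneous spacings.
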