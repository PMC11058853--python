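# Methods

## Model

A plate is a rectangular or circular grid (the circular mask is the disc
inscribed in the array). Two non-negative nutrient fields live on it: a
*top* layer that agents feed from and a *deep* layer standing in for the
bulk of the agar. The pair is a deliberately two-dimensional surrogate for
three-dimensional media: the deep layer lets nutrient reach the crowded
centre of a colony "from below" even after the top layer there is drained.

Each simulation step (≈ 1 hour) runs in a fixed, documented order:

1. scheduled events due at this step (refeed additions, strain/σ parameter
   switches, re-inoculations);
2. Gaussian diffusion of each layer with its own σ (grid cells / step);
3. inter-layer flow: per cell, `Δ = (deep/r − top)·flowrate/2` with
   `r = init_deep/init_top`; `top += Δ`, `deep −= Δ`;
4. agent life cycle per occupied cell: pro-rata nutrient allocation, energy
   update (uptake − state-dependent cost), then death check first, division
   second, G0/active classification last;
5. trajectory recording.

The relative order of transport and uptake within a step is a genuine
modelling choice; the order above is this package's reproducibility
contract.
Other such choices: death is checked before division so an agent cannot
divide in the step it starves; energy returned on death is clamped at zero;
daughters born in step *t* first act in *t + 1*; one global RNG stream per
run. Agents never move after placement; the cell an agent feeds from is
`(floor(x), floor(y))`.

### Numerical choices

- **Diffusion.** `scipy.ndimage.gaussian_filter`, kernel truncated at 4σ,
  reflective padding — the closed-dish (zero-flux) reading of "fixed
  boundaries", conserving total nutrient to < 1e−9 relative. On circular
  plates each in-mask source cell spreads its content over in-mask
  destinations only, renormalised per source (`out = m · K(g/(K·m))`),
  which is exactly mass-conserving and keeps out-of-dish cells at zero.
- **Flow clamping.** For extreme flowrates the transfer is clamped so both
  layers stay non-negative while preserving the pair sum; a warning is
  emitted. The pair sum is conserved to 1 ulp (floating-point rounding),
  which is what the "exact conservation" tests assert (rtol 1e−15).
- **Allocation.** Pro-rata scaling is computed with bincounts over the cell
  index; it is algebraically identical to visiting cells in any order.
- **Ledger.** The quantity (total agent energy) + (nutrient in both layers)
  + (cumulative metabolic spend) − (cumulative refeed additions) is tracked
  and closes to < 1e−6 relative over two simulated weeks. When an agent
  dies with negative energy the uncollectable deficit is booked against the
  spend term so the ledger stays exact.

## Parameters

Energy and nutrient share one abstract unit; lengths are grid cells; times
are steps (24/day). The default strain is the package's surrogate
energetic scale, chosen once for biological plausibility rather than fitted
to laboratory data:

| parameter | default | why |
|---|---|---|
| uptake_rate_active | 1.0 /step | sets the unit |
| metabolic_cost_active | 0.2 /step | net gain 0.8 → division every 2 steps ≈ the 2 h budding period of well-fed yeast |
| division_threshold | 2.0 | with initial_energy 1.0, asymmetric division returns the mother to the newborn state |
| initial_energy | 1.0 | daughter's endowment |
| g0_threshold | 0.7 | a starving newborn (1.0 → 0.8 → 0.6) quiesces on its second unfed step |
| death_threshold | 0.05 | G0 is the main fate under starvation; death needs active overspending or G0 attrition |
| uptake_rate_g0 / metabolic_cost_g0 | 0 / 0 | fully dormant quiescence (see below) |
| division_distance | preset: 0.8 dry / 0.9 wet | colony spreading rate proxy |
| sigma_top, sigma_deep | preset: 0.6/1.2 dry, 0.9/1.8 wet | within-layer transport |
| flowrate | 0.5 | inter-layer recharge; 0.2 on gradient plates |
| init_top / init_deep | 3 / 6 (Petri), 1.5 / 3 (OmniTray grid), 4 / 8 (gradient band) | see below |

Quiescence: with `uptake_rate_g0 = 0` the G0 state is absorbing — a colony
that quiesces before nutrient arrives can never regrow. Scenarios whose
point is delayed feeding (gradient plates, refeeding, wetness refresh,
multi-colony competition) therefore give G0 agents a small uptake
(0.1/step, zero cost): returning nutrient recharges them past the G0
threshold and they reactivate. The single-cell/droplet presets instead use
zero G0 uptake with a small G0 maintenance cost (0.003/step): the crowded
droplet interior quiesces at inoculation and slowly thins out, which is
what carves the central crater of the volcano-shaped density profile;
without interior attrition no crater can form in this model because
quiescent agents would persist at high density. Single-founder colonies
stay conical much longer since their interior quiesces only as the colony
ages.

Moisture: wetter agar is represented solely by a larger division distance
(daughters slide further on the wet surface) and larger diffusion σ. The
modest parameter difference (0.8→0.9 cells, σ×1.5) compounds into roughly a
doubling of the emergent radial expansion speed (≈0.6 vs ≈1.3 mm/day on the
50 mm disc presets), because rim daughters escape their mothers' depleted
cells more often *and* those fresh cells recharge faster. The alternating
presets swap the parameter set (and refresh the outer-ring nutrient) at day
7; growth rates track the current condition, not the history.

Nutrient levels: the Petri-dish value (3/6 per cell) makes a lone colony
decelerate over ~3 weeks on an 85 mm dish; the 24-droplet OmniTray uses
1.5/3 so that all 24 colonies decelerate within the first week — this early
nutrient limitation is what preserves the droplet-size advantage (day-2
area ratio ≈ 2.5 between 5 µl and 0.5 µl droplets, decaying to ≈ 2.1 by day
12) while founder count stays nearly irrelevant. Gradient plates put 4/8
(times the concentration multiplier) in the top fifth of rows and nothing
elsewhere; their deep layer uses a large σ (14) with a slow flowrate (0.2)
as the surrogate for plate-scale transport through the agar bulk — fast
enough that the 5×-concentrated band feeds the far rows within 20 days,
slow enough that the 1× band only feeds the near rows.

## Scales and resolution

Presets render plates at 0.425 mm per grid cell (an 85 mm dish on a
200×200 grid), so every preset runs in seconds-to-minutes on one CPU; the
area conversion used for mm² readouts is tied to that resolution
(≈ 5.54 px/mm²). The reference conversion of 55.6 px/mm² corresponds to a
~7.5× finer grid and can be requested with the `scale` argument of
`preset`/`run_scenario`; lengths in grid cells (division distance, σ,
droplet radii, positions) scale along, leaving the physical scenario
unchanged. One agent stands for a group of cells, not a single yeast cell;
simulated counts are morphology/area resolution choices, not cell counts.

## Measurement

Colony area is the number of grid cells holding at least
`min_agents_per_cell` (default 1) living agents of the colony. The radial
growth rate is the least-squares slope of the equivalent radius
√(area_mm²/π) against time in days over a stated window. Cross sections
are living-agent counts along a row through the colony centre; a local
maximum is a cell strictly above both neighbours after short moving-average
smoothing (3-cell default; the shape tests use 5 for spiky desk-scale
profiles). The inhibition-zone statistic samples total density along the
segment joining two colonies' centroids and compares the minimum over the
middle half against the smaller colony's median occupied-cell density.

## Calibration

The objective is Σ (simᵢ − refᵢ)² over colony areas in pixels, summed over
all colonies, with simulated series sampled at `round(day·24)` steps.
Nelder-Mead runs on log-transformed parameters (all fit-able parameters are
positive, so bounds are free), with an explicit ±0.25 log-space initial
simplex — scipy's default multiplicative perturbation collapses near
log-values of 0. Each evaluation averages the simulated series over a fixed
set of seeds (default 3) so the simplex sees a quasi-deterministic surface;
failures are penalised with a large finite value. Stopping: simplex size
< 1e−3 (log space) or 200 evaluations.

The synthetic-target generator runs the simulator at known parameters,
samples daily areas, and adds independent Gaussian pixel noise; it records
the generating truth. The standard recovery setups (60×60 plate, one
50-founder droplet) recover the division distance within a few percent
from a 50%-off start. Sigma is identifiable only when the colony is
diffusion-limited, so its setup decouples the deep layer (flowrate 0) and
averages 5 seeds per evaluation; because the target itself is a single
stochastic realisation, the recovered σ is usually within ~3% but can miss
by ~15–20% for unlucky target seeds.

## What the synthetic scenarios do and do not show

The presets emulate plate geometry, inoculation layouts, moisture-dependent
spreading, nutrient placement and refeeding schedules. They do not emulate:
physical forces between cells or with the agar (no pushing, no 3-D
structure), extracellular-matrix mechanics, signalling molecules such as
ammonia, time-dependent drying, stochastic event probabilities, or
epigenetic differentiation — colony interaction is purely nutrient
competition. Passing tests therefore demonstrate the internal consistency
of that mechanism and the qualitative orderings it produces (crowding
shrinks colonies, droplet size beats founder count, wet beats dry,
gradients steer growth, colonies do not interpenetrate); they do not
validate the surrogate parameter values against laboratory measurements.

## Known limitations

- Simulated colony edges are more ragged than real ones (no matrix holding
  a sharp front); the occupied-cell area is accordingly noisier than
  image-thresholded areas at equal physical size.
- The pair-sum conservation of the inter-layer flow holds to 1 ulp, not
  bitwise; all "exact" checks are at machine precision.
- Nelder-Mead is local; starts far from plausible colony sizes can stall
  on the stochastic plateau of the objective.
- Desk-scale problem sizes (60–300 grid cells per side, 2–6 week horizons,
  3–5 seeds) are package defaults chosen for interactive use; finer grids
  via `scale` change runtimes roughly with cell count.
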