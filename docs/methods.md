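# Methods

## Model

`coralpump` integrates a single reactive organic-carbon tracer offline: the
velocity field is prescribed (synthetic or loaded), never computed from
momentum equations. The water column over a 2-D bathymetry `H(x, y)` is
divided into `N` terrain-following layers; layer thicknesses
`Hz = H · Δσ(k)` follow a monotone stretching of the non-dimensional
coordinate σ ∈ [−1, 0] (the classic two-parameter hyperbolic form of
terrain-following ocean models, with surface/bottom refinement controlled
by θs and θb and no critical-depth term, so thicknesses are strictly
proportional to the local depth). Scalars live at cell centres, `u` and `v`
on the x- and y-faces, and `w` on the horizontal interfaces (Arakawa
C-grid). The layer index runs bottom-up; depths are positive down; the free
surface is rigid (η ≡ 0), so the grid never stretches in time.

The vertical velocity is diagnostic. With the bottom interface closed
(`w = 0` at the seafloor), the volume flux through interface `k+1` equals
the flux through interface `k` minus the net horizontal volume-flux
divergence of layer `k`; dividing by the cell area gives `w`. For any flow
whose depth-integrated transport is non-divergent, the surface value of
this sum vanishes; the residual (order 10⁻¹⁵ m s⁻¹ for generated flows) is
reported as a diagnostic, not forced to zero.

Tracer dynamics per sub-step, in this fixed operator order:

1. **Advection** (flow + sinking) by donor-cell upwind fluxes on all faces.
   Sinking is folded into the vertical face velocity (`w − w_s` on interior
   interfaces, in consistent units); the bottom face carries the effective
   settling velocity alone, and its flux leaves the water column
   permanently as deposition (no resuspension). Lateral and surface
   boundaries are zero-gradient: ghost cells copy the adjacent interior
   value, so outflow exports the boundary-cell concentration and inflow
   imports the same value.
2. **Decay**, applied analytically (multiplication by `exp(−k Δt)`), which
   is unconditionally stable and composes exactly across sub-steps.
3. **Surface input**: the top cell of every column gains
   `F₀ Δt / Hz_top`.

No explicit horizontal or vertical diffusion is added; the first-order
scheme's numerical dispersion plays that role.

Suspension feeding by the coral community is an enhanced bottom settling
velocity: feeding rates in m³ m⁻² d⁻¹ are dimensionally a velocity, so
multiplying the settling velocity by an enhancement factor E in bottom
cells over coral habitat (default E = 10, giving 200 m d⁻¹) represents
community filtration. An order-of-magnitude check: a square metre of reef
under a 0.3 m s⁻¹ current feeding from the bottom 0.2 m has
0.3 · 0.2 · 86400 = 5184 m³ d⁻¹ available, so 200 m d⁻¹ of clearance is a
capture efficiency of 3.86% — physically modest.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| w_s | background sinking velocity | 20 | m d⁻¹ |
| k | first-order decay rate | 0.03 | d⁻¹ |
| F₀ | surface export flux | 12 | mmol C m⁻² d⁻¹ |
| E | suspension-feeding enhancement | 10 | – |
| θs, θb | vertical stretching | 3.4, 1.0 | – |
| N | vertical layers | 32 (20 in the desk-scale scenario runs) | – |
| Δx, Δy | horizontal spacing | 250 | m |

w_s/k ≈ 667 m is the e-folding depth of the sinking flux, in the 500–700 m
range typical of biogeochemical circulation models; F₀ is equivalent to
≈ 52.6 g C m⁻² yr⁻¹ of new production. With no flow the model reduces to the
closed form `F(z) = F₀ e^(−k z / w_s)`, `C(z) = F(z)/w_s` (surface maximum
0.6 mmol C m⁻³), which doubles as the analytic oracle and as the initial
condition of every run.

## Synthetic study conditions

The generator emulates the inputs of a mid-latitude shelf-slope CWC
province at desk scale (15 × 10 km, 60 × 40 columns):

* **Bathymetry**: a tanh slope from a 200-m bank to a 2000-m trough, one
  Gaussian mound of 380-m relief placed where the background is 980 m
  (summit ≈ 600 m, radius 900 m), and a ridge cresting near 450 m at the
  shelf break. The slope half-width (a quarter of the domain) keeps the two
  features' footprints separate.
* **Tidal flow**: the depth-integrated transport derives from a
  streamfunction, so it is non-divergent to round-off and all diagnosed
  vertical motion is topographic. The streamfunction profile follows the
  *background* (along-flow median) depth across the flow, making the
  depth-averaged speed uniform over smooth slope and amplified by
  `H_background/H` over mounds — tidal acceleration over topography. The
  envelope is semidiurnal (12.42 h) with a 14.77-d spring–neap modulation of
  depth 0.4. The default axis is cross-isobath, the tidal-ellipse component
  that actually drives flow over the mound and spillover across the ridge.
  A surface-intensified vertical profile `φ(z) = 1 + e^(−z/300 m)`
  (normalised per face, so transport is unchanged) gives the velocity the
  depth dependence without which a sigma grid carries every layer a fixed
  transport fraction and no layer ever diverges — i.e. no up/downwelling at
  all. The amplitude (0.4 m s⁻¹) is calibrated so the time-mean near-bottom
  speed above the coral habitat is ≈ 0.3 m s⁻¹. Snapshots are stored at 6-h
  cadence and linearly interpolated to each integration step.
* **Habitat**: coral columns are those inside a 400–1000 m depth window
  that stand proud of the background slope, thinned to 40% coverage by a
  deterministic spatial hash — emulating a habitat-suitability model's
  *scattered* presence predictions on summits, flanks and ridge rather than
  a closed blanket. Columns are classed `coral_mound`, `coral_ridge` or
  `off_reef`. All generators are seed-free: identical configurations give
  bit-identical fields.

What the generator does **not** emulate: internal waves, hydraulic jumps
and stratification (the up/downwelling here is the kinematic response of a
sheared tide to topography, with |w| maxima near 1 cm s⁻¹ — an order of
magnitude weaker than a full hydrodynamic model produces over such mounds);
residual (time-mean) currents, unless a constant background transport is
configured; wind and waves; and any feedback of the corals on the flow.
Passing tests therefore demonstrate the mechanism and the numerics, not
field-scale magnitudes.

## Scenario runs and analyses

The three standard scenarios share one grid, mask and parameter set:
baseline (hydrodynamics + filtration), `no_filtration` (E effectively off)
and `no_hydro` (zero velocity everywhere; sinking, decay, surface input and
filtration retained). Desk-scale runs integrate two spring–neap cycles
(29.54 d) after a 5-d spinup excluded from averages, at 20 vertical levels
— a few minutes on one CPU. The sub-step is chosen per 6-h flow interval
from the donor-cell stability bound (per-cell total-outflow Courant number
≤ 0.8, capped at 0.05 d), which guarantees positivity and monotonicity.

Deposition is accumulated per column as the bottom-face settling flux and
time-averaged after spinup; the focusing analysis bins columns into 100-m
depth bins and compares coral and off-reef bin means *within* bins
containing both classes, summarised as the mean of per-bin ratios. The mass
budget (inventory, surface input, decayed, deposited, net lateral export)
closes to round-off (≤ 10⁻¹³ relative) at every output time.

Measured study-condition results (all computed by the test suite and
`scripts/acceptance.py`, never asserted from memory): bin-mean focusing
ratio 3.9 (per-bin 3.1–4.7); with filtration off the bin-mean ratio is 1.05;
off-reef deposition beyond 1200 m exceeds the no-hydrodynamics run in every
bin (by 2–81%).

## Numerical choices and accuracy

* First-order upwind everywhere; one advection step on any small instance
  matches an independent loop-based donor-cell implementation to 10⁻¹².
* The quiescent column converges to the closed form with a truncation error
  controlled by the total decay exponent `kH/w_s`: at 32 levels the
  L∞ relative error is ≈ 1.7% for a 600-m column (the coral summit depth),
  ≈ 3.9% at 1000 m and ≈ 17% at 2000 m. Errors shrink roughly linearly
  with vertical refinement.
* Operator splitting (advect → decay → surface flux) is first-order,
  consistent with the advection scheme; decay is exact within each step.
* Tie-breaks: upwind faces with exactly zero velocity take the downwind
  cell (the flux is zero either way); boundary faces always use the
  adjacent interior cell as donor (zero-gradient ghosts).
* Degenerate inputs: zero flow returns the configured time-step cap; an
  empty habitat mask warns and proceeds (filtration is a no-op); columns
  must be strictly positive in depth.

## Known limitations

* The synthetic tide's downwelling is ~30× weaker than over real coral
  mounds, so the scaled-down focusing ratio (≈ 3.9) approaches the
  field-scale factor 5–10 from below: vertical delivery of carbon-rich
  surface water — the dominant supply at full strength — is
  under-represented relative to horizontal near-bottom replenishment.
* Deposition is permanent; there is no resuspension, no refractory OM pool
  and no coral physiology — the tracer is fresh, reactive organic carbon
  only.
* The rectilinear grid ignores curvature; the enhancement applies to the
  bottom face only (equivalent to enhancing the bottom-cell sink where the
  bottom layer is thin).
* Zero-gradient open boundaries recycle the boundary-cell concentration on
  inflow; strong cross-domain flows therefore behave as if the upstream
  ocean matched the domain edge.
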