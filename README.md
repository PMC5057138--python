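# coralpump

An offline reaction–transport model for fresh organic carbon over
cold-water-coral (CWC) topography.

Cold-water corals build carbonate mounds hundreds of metres tall in the
food-limited deep ocean. How does enough surface-produced organic matter (OM)
reach them? `coralpump` simulates the mechanism: tidal currents flowing over
mounds and ridges force up- and downwelling that carries fresh, sinking
organic carbon down the water column, while the suspension-feeding reef
community strips it out of the near-bottom flow. The result is a "focusing"
of OM deposition onto coral habitat at the expense of the surrounding
seafloor at the same depth, plus a leak of carbon to the deeper seafloor —
a topographically-enhanced carbon pump.

## Model

The organic-carbon concentration `C` (mmol C m⁻³) on a terrain-following
(sigma) Arakawa C-grid evolves under

* **advection** by horizontal currents `u, v` with the vertical velocity `w`
  diagnosed per column from the flux divergence of the horizontal flows
  (rigid lid, `w = 0` at the seafloor), discretised with first-order upwind
  (donor-cell) fluxes — the scheme's numerical dispersion stands in for
  explicit diffusion;
* **passive sinking** at `w_s = 20 m d⁻¹`;
* **first-order decay** at `k = 0.03 d⁻¹` (e-folding depth `w_s/k ≈ 667 m`);
* a **constant surface export flux** `F₀ = 12 mmol C m⁻² d⁻¹`
  (≈ 50 g C m⁻² yr⁻¹);
* **suspension feeding**: in bottom cells over coral habitat the settling
  velocity is enhanced by a factor 10 (to 200 m d⁻¹); the bottom-face flux
  is recorded as deposition.

With no flow, the model has the closed-form steady column
`F(z) = F₀ exp(−k z / w_s)`, `C(z) = F(z)/w_s`, used as an analytic oracle.

A synthetic-data module generates the study conditions: a 200–2000-m
shelf-slope bathymetry with a 380-m Gaussian coral mound (summit ≈ 600 m)
and a shelf-break ridge (crest ≈ 450 m), a transport-conserving semidiurnal
tidal flow with a spring–neap envelope stored at 6-h cadence, and a
scattered coral-habitat mask on summits, flanks and ridge. Externally
supplied NetCDF grids and flows are accepted as well.

## Worked example

```python
import numpy as np
from coralpump import OMParams, capture_efficiency, steady_column_solution
from coralpump.analysis import deposition_vs_depth, focusing_factor
from coralpump.study import run_study_scenario

params = OMParams()
conc, flux = steady_column_solution(params, np.array([0.0, 600.0]))
print(round(conc[0], 3))                                    # 0.6  mmol C m-3
print(round(params.efolding_depth, 1))                      # 666.7 m
print(round(capture_efficiency(0.3, 0.2, params.ws_coral), 2))  # 3.86 %

baseline = run_study_scenario("baseline")   # ~2 min on one CPU
table, summary = deposition_vs_depth(baseline)
print(summary[summary.n_coral > 0].round(3).to_string(index=False))
print(round(focusing_factor(baseline), 2))
```

which prints (deposition in mmol C m⁻² d⁻¹):

```
 depth_bin  off_reef_mean  coral_mean  ratio  n_coral  n_off_reef
     400.0          2.738      12.851  4.694      1.0         127
     500.0          2.476       9.065  3.662     30.0          84
     600.0          2.464       8.664  3.516     14.0          76
     700.0          2.420       7.621  3.149      9.0          69
     800.0          2.402       9.973  4.151      8.0          62
     900.0          2.292       9.426  4.112      5.0          41
3.88
```

Coral columns receive three- to five-fold more organic carbon than off-reef
seafloor in the same 100-m depth bin; turning filtration off
(`run_study_scenario("no_filtration")`) collapses the separation, and
turning hydrodynamics off (`"no_hydro"`) cuts deposition beyond 1200 m by
up to ~45% — the deep leak of the topographic pump.

The same pipeline is scriptable from the shell:

```bash
coralpump make-inputs --out inputs          # bathymetry, tidal flow, habitat
coralpump run --inputs inputs --out run     # baseline scenario
coralpump analyze run                       # CSV tables + figures
```

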