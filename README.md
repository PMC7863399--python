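# sympatry

Niche-overlap analysis for sympatric carnivores sharing prey and space —
wolves (*Canis lupus*) and coyotes (*C. latrans*) competing over
white-tailed deer being the motivating system. The package implements the
full analytical chain a field study of interference competition needs,
for movement ecologists working from GPS/accelerometer collar data, scat
surveys and landscape rasters:

- **Occurrence distributions (ODs)** from the dynamic Brownian bridge
  movement model (dBBMM): the motion variance σ²ₘ is estimated along the
  path by a sliding-window change-point likelihood, then the bridge
  density between consecutive fixes is integrated onto a 30 m grid and
  its 99% contour taken as the boundary of available area. A static
  Brownian bridge variant (single σ²ₘ, 48 h maximum lag) handles sparse
  VHF triangulations.
- **Resource utilization functions (RUFs)**: OLS of OD height on
  standardized landscape and prey covariates over in-contour cells;
  population inference averages individual coefficients,
  β̄ᵢ = (1/n) Σⱼ β̂ᵢⱼ with Var(β̄ᵢ) = 1/(n−1) Σⱼ (β̂ᵢⱼ − β̄ᵢ)², treating
  animals as random draws from the population. Predicted wolf occurrence
  enters each coyote model as an avoidance covariate, so wolf models are
  always fit first. Fit is validated by leave-one-individual-out
  cross-validation with 8-bin rank regression.
- **Activity overlap**: collar accelerometer summaries are classified
  active at a summed-acceleration threshold (≥ 30.7); daily activity
  densities are von Mises kernel estimates on the 24 h circle, compared
  by the coefficient of overlapping Δ = ∫ min(f̂₁, f̂₂).
- **Diet overlap** from scats: species assignment by tracks or diameter
  (with a 28.1–29.0 mm exclusion band), per-item percent-volume
  proportions, dietary breadth B = 1/Σpᵢ² and Pianka's overlap
  α = Σpᵢqᵢ / √(Σpᵢ²·Σqᵢ²).
- **A synthetic-data generator** (first-class, tested) producing
  landscapes, two-state movement tracks with habitat preference,
  accelerometer streams and Dirichlet-composition scats, so the entire
  pipeline runs and is validated without any field data.

## Worked example

```python
import numpy as np
from sympatry.simulate import SyntheticScenario, simulate_track
from sympatry.movement import fit_dynamic_motion_variance, occurrence_distribution

scenario = SyntheticScenario(rng_seed=7)
sim = simulate_track(scenario, "W01", "wolf", "2014-05-05T00:00:00",
                     n_fixes=288, rng=np.random.default_rng(7))
profile = fit_dynamic_motion_variance(sim.track, window=23, margin=5)
od = occurrence_distribution(sim.track, profile, od_level=0.99, cell=30.0)
print(f"median motion variance: {np.median(profile.sigma2):.1f} m^2/min")
print(f"99% contour: {int(od.level_mask.sum())} cells "
      f"({od.level_mask.sum() * 0.09:.1f} ha)")
```

```
median motion variance: 53.2 m^2/min
99% contour: 298 cells (26.8 ha)
```

The motion variance is the diffusion rate of the bridge process — the
median here reflects a collar alternating between travel (σ²ₘ ≈ 150
m²/min in this scenario) and rest; the contour area is the animal's
three-day utilization footprint at the 99% level.

Or run everything from the shell:

```bash
sympatry simulate --out-dir study --seed 7
sympatry run-all --gps study/gps.csv --activity study/activity.csv \
    --scats study/scats.csv --rasters study/rasters --out-dir study/results --seed 7
```

`study/results/` then holds, per period: activity overlap Δ, per-species
diet proportions with B and α, individual and population RUF coefficient
tables with 95% CIs, prediction surfaces (ESRI ASCII grids), and
cross-validation slopes/R².

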