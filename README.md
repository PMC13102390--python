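# antnest

Modelling and analysis of nest excavation by ant colonies with explicit
demographics.

Carpenter-ant colonies (*Camponotus fellah*) regulate the size of their nest
as they grow: the excavated area stays roughly proportional to the number of
ants, and which ants do the digging depends on their age. `antnest`
implements an age-dependent density-regulation model of this process, the
synthetic-data generators needed to study it (colony timelines and nest
images), the inference procedures that recover its parameters from
excavation time series, and an image pipeline that measures and classifies
nest structure from photographs.

## The model

Each ant digs at a rate set by how far the current area per ant falls short
of her own age-dependent target,

    da/dt = r (1 − a / a_age),        a_age = max(0, 11.22 − 0.032 · age)

where `a = A/N` is the shared area per ant (cm², the reciprocal of density),
`r = 2.2 cm²/(ant·day)` is an age-independent basal digging rate (the
maximum rate, realised in an empty nest), and `a_age` is the target area of
an ant of a given age in days. Negative rates are rectified to zero
(backfilling is negligible). A colony of N ants digs at the sum of the
individual rates:

    dA/dt = Σᵢ r (1 − a / a_age(i))

The stable fixed point is reached when the area per ant equals the largest
target in the colony — the youngest ant's. Old ants therefore stop digging
long before young ones: ordinary nest growth is carried by the young, while
after a catastrophic collapse (removal of 25–30% of the area) *every* ant
is below target and digs until the plateau is restored. An age-independent
null model (constant target, 11.6 cm²/ant) is included for comparison; it
is the special case of a zero-slope target line.

Colony demographics enter through timelines: a founding queen (who excavates
~23.8 cm² alone before the first workers eclose, then stops), workers that
emerge along a logistic population curve saturating at 5–20 ants over ~190
days, and a ~10-day maturation delay before a newly eclosed worker digs.
Fixed-demographics groups (5/10/15 ants including the queen, workers all
"young", 40 ± 16 d, or "old", 171.56 ± 20 d) isolate the age effect.

## Worked example

```python
import dataclasses
import numpy as np
from antnest import demography as dg, excavation as ex, inference as inf

cfg = dg.GeneratorConfig(seed=42)
colony = dg.synth_fixed_colony(10, "young", cfg, age_sd=0.0)  # all workers 40 d
colony = dataclasses.replace(colony, duration_days=90.0)
params = ex.ModelParams()
result = ex.simulate(colony, params)
sat = ex.saturation_area(result)
print("saturation area: %.1f cm^2 (%.2f cm^2 per ant)" % (sat, sat / 10))

ev = ex.CollapseEvent(day=45.0, fraction=0.28)
res2 = ex.simulate(colony, params, events=[ev])
print("post-collapse recovery fraction: %.3f" %
      inf.recovery_fraction(res2.days, res2.total_area, ev))

rng = np.random.default_rng(1)
obs = ex.observe(result, np.arange(0.0, 31.0, 2.0), 0.05, rng)
fit = inf.estimate_r(obs["day"], obs["area_cm2"], N=10)
print("recovered basal rate r = %.2f cm^2/(ant day)" % fit.r)
```

prints

```
saturation area: 99.1 cm^2 (9.91 cm^2 per ant)
post-collapse recovery fraction: 0.999
recovered basal rate r = 2.00 cm^2/(ant day)
```

The ten-ant group (an old queen plus nine 40-day-old workers) saturates at
9.91 cm² per ant — the 40-day target `11.22 − 0.032·40 = 9.94` up to the
plateau-detection window. After 28% of the nest is collapsed the group
re-excavates essentially all of the lost area (fraction 0.999 of the loss).
A closed-form saturation-curve fit to a noisy 30-day observation of the
same trajectory recovers the basal rate within the sampling scatter of a
single replicate (the published uncertainty is ±0.43 around 2.2).

A command-line interface mirrors the library (`antnest synth / simulate /
fit / analyze / segment`); `antnest synth --seed 0 --out runs/demo` writes a
full synthetic study (22 colony-maturation and 37 fixed-demographics
colonies, trajectories, and a labeled nest mask).

## Nest-structure pipeline

`antnest.nest_structure` goes from photograph to morphology: projective
registration on the frame's support blocks (normalized DLT), background
subtraction and adaptive thresholding into a binary excavation mask, area
measurement from the pixel count, then skeletonization, branch splitting at
junctions, per-branch width (distance transform) and orientation (principal
axis, folded into [0°, 90°] with 90° pointing down the image, i.e. along
gravity), and classification into chambers (wide, near-horizontal), wide
tunnels, and tunnels. A synthetic nest generator with per-pixel ground
truth validates the pipeline (pixel-class accuracy ≥ 90%, orientation MAE
≤ 5° on the bundled fixture).

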