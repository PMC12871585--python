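# conewell

Analysis toolkit for conical-microwell-array live-cell screens: detect
the microwell lattice in brightfield time-lapse stacks, track per-well
cell counts and clonal growth, quantify cytokine secretion rings and
surface markers, apply hierarchical gates, and export picker worklists
— with a seeded synthetic scene generator that provides ground truth
for every stage.

## The problem

Microwell-array platforms co-culture tens of thousands of single cells
(one conical microwell ≈ 65 µm bottom diameter, 130 µm pitch) and image
them for days, so that rare clones — a fast-growing cell line variant,
or a T cell that secretes IFN-γ when it meets its cognate antigen — can
be found and physically retrieved with a picker. The computation sits
between the camera and the picker: every microwell needs a stable
identity across timepoints, every timepoint needs per-well cell counts
and intensities, and the resulting features need to be gated into a
pick list the instrument can execute. `conewell` implements that chain
for anyone who wants to prototype or audit such an analysis at desk
scale.

## Models and statistics

**Poisson loading.** Seeding N cells over M equiprobable microwells
gives per-well occupancy k ~ Poisson(λ), λ = N/M. The expected number
of single-cell wells, M·λe^(−λ), is maximized at λ = 1: load as many
cells as there are microwells.

**Clonal growth.** Each microwell trajectory n(t) is fit two ways:

* *division rate* r — the OLS slope of log₂ n(t) against time in days,
  in divisions/day (zero counts excluded; negative r = death);
* *normalized mean count* g — mean of n(t) over all timepoints divided
  by n(t₀); g > 1 growth, g < 1 death.

A microwell is called proliferative only when **both** r ≥ r_min and
g ≥ g_min, which suppresses single-frame artifacts that can fake either
statistic alone.

**Secretion rings.** Cytokine captured on the conical walls is measured
as the mean intensity I(t) of a wall annulus; the relative signal
S(t) = I(t) − I(t₀) removes static background. Cross-talk — cytokine
captured from a secreting neighbour — arrives as a one-sided arc, so a
rotational-symmetry score σ_sym (coefficient of variation of the
annulus intensity across 8 angular sectors) gates it out: positives
need S above a control-derived threshold (mean + 5 SD of unstimulated
controls) **and** σ_sym ≤ 0.5.

**Gating and enrichment.** Gate trees are conjunctive threshold
predicates over (feature, timepoint) pairs evaluated top-down, with
half-up-rounded percentages per gate; library enrichment compares bulk
vs recovered member frequencies as fold change and calls a dominant
member per microwell.

## Worked example

```python
import numpy as np
from conewell import scene_sim, gridmap, kinetics, loadstats

print("expected_singles(4000, 4000) =", round(loadstats.expected_singles(4000, 4000), 1))

cfg = scene_sim.preset("nalm6_default", grid_rows=8, grid_cols=8,
                       n_timepoints=13, seed=42)
stack, _, truth = scene_sim.render_scene(cfg)
layout = gridmap.PlateLayout(pixel_size_um=cfg.pixel_size_um)
grid = gridmap.detect_grid(stack.frame(0, "BF"), layout)
print(f"detected {len(grid)} microwells, pitch {grid.pitch_px:.1f} px")

times = truth.times_hours
singles = truth.table.occupancy_t0.to_numpy() == 1
ests = [kinetics.estimate_growth(truth.trajectories[i], times, i)
        for i in np.flatnonzero(singles)]
r = np.array([e.r for e in ests if e.r is not None])
flags, _ = kinetics.classify_proliferative([e for e in ests if e.r is not None])
print(f"{singles.sum()} single-cell microwells; median r = {np.median(r):.2f} div/day")
print(f"proliferative (r>=0.25, g>=1.2): {flags.sum()} of {len(flags)}")
```

prints

```
expected_singles(4000, 4000) = 1471.5
detected 64 microwells, pitch 65.0 px
20 single-cell microwells; median r = 0.87 div/day
proliferative (r>=0.25, g>=1.2): 19 of 20
```

At λ = 1 loading, ~1471.5 of 4000 wells are expected to hold exactly
one cell (4000·e⁻¹). The detector recovers all 64 lattice sites at the
configured 65-px pitch; of the 20 single-cell wells in this small
scene, the fitted division rates have a median of 0.87 div/day
(the preset draws rates lognormally around 0.8) and 19 pass the dual
proliferation gate.

The same stages are scriptable from the shell:

```bash
conewell simulate --preset nalm6_default --out scene.zarr --truth truth.csv --seed 1
conewell detect --stack scene.zarr --out grid.csv
conewell run --config run.yaml     # full detect→gate→picklist pipeline
```

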