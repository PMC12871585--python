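# Methods

This note documents the models behind `conewell`, the choices made
where the design was genuinely open, and what the synthetic scenes do
and do not establish about real data.

## Geometry and coordinates

The array is modelled as a square lattice (hex selectable) of conical
microwells with 130 µm pitch and 65 µm bottom diameter. The default
working scale is 2.0 µm/px, i.e. 65 px pitch — a deliberate 4× coarsening
of the 0.5 µm/px native optics so that a 500-microwell scene fits
comfortably in memory; the native scale is one config field away.
All coordinates are 0-based (y, x) pixels with origin at the top-left;
micron quantities are converted only at module boundaries via
`pixel_size_um`. Images live in TCZYX zarr groups with NGFF-style
multiscale attributes; the Z axis is carried but downstream operations
consume a single (max-projected) plane, since acquisition autofocuses
and analyzes 2-D stitches.

## Synthetic scenes

`scene_sim` emulates the instrument's output: brightfield microwells as
dark rings on a bright background (ring contrast 80 over a background of
200), cells as dark ~10 µm disks packed at the well bottom, marker
channels as bright disks for the labelled clones, and a cytokine
channel in which secretion-positive wells gain a wall annulus whose
mean grows linearly at `accumulation_rate` (default 8 intensity
units/h). Cross-talk victims receive a one-sided arc covering 25% of
the ring circumference carrying the *same total signal* as a full ring,
so they defeat a pure intensity gate and exist precisely to be rejected
by the symmetry gate. Stage drift is a global integer-pixel shift per
frame; Gaussian noise (σ = 2 by default) is added last. One integer
seed drives a single generator per scene, so equal configs render
bit-identical stacks.

Planted conditions use exact counts — `round(fraction · n)` positives
and victims assigned by a seeded permutation — rather than Bernoulli
draws, so a preset's fraction is the scene's true fraction and recovery
checks measure the caller, not binomial jitter.

Presets encode the study conditions: `nalm6_default` draws
per-microwell division rates lognormally with median 0.8 divisions/day,
σ_log = 0.4, and a 5% death fraction (rates negated); the median is the
anchored quantity, while the dispersion and death fraction are chosen
once as realistic for an established suspension line. `peptide_pulsed`
renders 1:1 co-cultures with 40% secretion-positive and 5% cross-talk
wells, imaged every 4 h for 24 h.

What the scenes do **not** model: photorealistic optics of the conical
walls, per-division stochasticity (growth is deterministic exponential
with a random per-well rate, matching the estimator's model class so
recovery tests are interpretable), cell migration between wells,
adherent-cell morphology, and phototoxicity. Passing recovery tests
therefore demonstrates correctness of the estimators and gates under
the stated noise model, not robustness to every imaging pathology of a
physical instrument.

## Grid detection and registration

Detection is classical: the inverted brightfield frame is smoothed with
a Gaussian of σ equal to the ring radius (σ must exceed radius/√2 or
the smoothed ring keeps a crater ridge instead of a central peak),
local maxima above 30% of the response span become candidates, and
centers are refined by iterated centroiding restricted to the wall-ring
band — restricting to the band keeps cells at the well bottom from
biasing the center. Pitch is the median nearest-neighbour spacing
(rejected if >20% off the configured layout); rotation (supported to
±5°) is the median neighbour angle folded onto the nearest axis; IDs
are assigned row-major after rotation correction and never reassigned.
A `detector` hook accepts a drop-in replacement (e.g. a learned
detector) returning candidate centers and scores.

Registration estimates one global integer shift per timepoint by FFT
cross-correlation against the stored t0 frame, restricted to ±(pitch/2
− 1) px to rule out lattice-period aliasing; a normalized peak below
0.1 logs a warning and assumes zero drift. Per-microwell registration
is deliberately not attempted: drift is mechanical, so the frame moves
as a whole.

Accessibility: the picker tip cannot reach wells near the perimeter.
"Central 75% of the footprint" is interpreted as an *area* fraction —
a site is accessible inside radius √0.75 ≈ 0.866 of the bounding-circle
radius — because on a ~3,958-site circular well that yields ≈2,970
reachable sites, closest to the instrument's quoted working region.
The fraction is config.

## Cell counting and intensities

Cells sediment to the cone apex, so segmentation is restricted to the
central bottom zone (default radius 0.22 × crop side, just inside the
wall ring for the standard bottom/pitch ratio of 0.5). Foreground is
`inverted intensity > 5·MAD` above the crop median, split by watershed
on the distance transform, then size-gated to 5–20 µm equivalent
diameter (below: debris; above: artifact). The count is deterministic
given pixels; ≥50 objects sets a `crowded` flag, since dense colonies
merge and the count saturates — a documented limitation, not an error.
Fluorescence per cell is the mean over the brightfield mask footprint
minus the out-of-mask crop median, which is robust to secretion-ring
light at the crop edges. Marker thresholds default to background median
+ 5·MAD per plate and are otherwise user-supplied.

## Growth estimation

`r` is the OLS slope of log₂(count) vs time in days over timepoints
with count ≥ 1 (log-space OLS makes the slope directly divisions/day);
zero counts are excluded rather than imputed. `g` is the plain mean of
the count over all timepoints, t₀ included, divided by the t₀ count —
the "weighted average" is taken with uniform weights, and the inclusion
of t₀ is switchable (`include_t0_in_mean`). The dual gate defaults
(r ≥ 0.25 div/day, g ≥ 1.2) are this package's own defaults for a
threshold the operator sets interactively in practice; both appear in
the provenance record of every pipeline run.

## Secretion calling

The wall annulus spans 0.25–0.475 of the pitch radially (bottom-radius
to just inside the rim) with 8 angular sectors — enough angular
resolution to flag a quarter-circumference arc while keeping ≥250
pixels per sector at desk scale. σ_sym = SD/mean of sector means; a
non-positive mean returns +∞ so flat crops can never pass. σ_sym is
evaluated on the `crop(t) − crop(t0)` difference image: differencing
removes the static background that would otherwise dilute the sector
CV of an accumulated arc. Positives require S(t) ≥ threshold AND
σ_sym(t) ≤ 0.5 at a single timepoint (persistence across consecutive
timepoints is available via the calling window but not default). The
intensity threshold defaults to mean + 5·SD of S over
occupied-but-unstimulated control wells at the matched timepoint; an
absolute override exists for runs without controls.

## Loading statistics and enrichment

Occupancy tables truncate the Poisson pmf at k_max = max(20, ⌈λ +
10√λ⌉) with the tail folded into the last bin, so tables sum to 1
exactly. The goodness-of-fit helper pools bins with expected count < 5
from the right before the chi-square. Fold enrichment for members
absent from the bulk pool is a +∞ sentinel (library dropouts are real),
absent from the recovered pool is 0. The dominant-antigen call requires
the top member to hold ≥ 50% of a microwell's reads; ties and zero-read
rows are "ambiguous".

## Pipeline

Stages run detect → register → quantify → growth → secretion → gate →
picklist over one long-format feature table keyed by (well,
microwell_id, timepoint). Artifacts are append-only; a stage whose
artifact exists is skipped on resume; a provenance JSON captures the
package version, config hash and seed. Gate predicates are
conjunctions of threshold comparisons with `@t<k>`, `@first`, `@last`
and `@any(t≥h)` selectors — disjunction via sibling gates — which
covers the cascades this workflow needs without a general expression
language. Pick lists are CSV (an invented schema, as the instrument's
native format is not public): stage coordinates are the t0 center plus
the last registered shift in microns, interleaving alternates labels
round-robin, and blank controls are accessible *empty* wells inserted
at seeded-random positions. Accessibility is a hard invariant: an
inaccessible selection is refused, never silently dropped.

## Problem sizes and numerics

Recovery checks run at 2,000 trajectories for growth (analytic
pipeline) and a 25×20 rendered scene (500 co-cultures) for secretion;
these sizes give sampling error well inside the stated tolerances
while keeping a full test run under a minute of rendering. Counts are
rounded half-up and a trajectory that reaches zero stays zero.
Percentages are rounded half-up via decimal arithmetic, matching how
gate cascades are conventionally printed. Known limitations: touching
cells can merge (count accuracy is asserted only for non-touching
configurations), rotation beyond ±5° is unsupported, and the secretion
caller assumes the annulus is concentric with the detected center.
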