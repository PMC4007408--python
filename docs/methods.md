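# Methods

`axodyne` quantifies axon degeneration and axonal mitochondrial dynamics in
larval zebrafish Rohon-Beard sensory neurons expressing human wild-type
α-synuclein (aSyn), with or without the protective proteins WldS and
PGC-1α.  Because the original imaging data are not publicly available, every
measurement stage is paired with a synthetic-data generator whose parameters
encode the published summary statistics; the pipeline is validated by
recovering those parameters through the full measurement chain.

## Condition profiles

Each condition (WT, aSyn, aSyn+WldS, aSyn+PGC1a) is a `ConditionProfile`
bundling transport kinetics, morphology, a 5-point axonopathy stage model,
Wallerian-degeneration (WD) timing, and 2→3 dpf survival.  The shipped
values (`src/axodyne/data/condition_profiles.yaml`) are the in-vivo
measurements for each condition; where a study did not measure a quantity
for a condition, the nearest measured condition's values are reused:
aSyn+WldS reuses the aSyn transport and morphology blocks (WldS acts
downstream of the mitochondrial phenotype), and aSyn+PGC1a reuses the WT
blocks (PGC-1α restores mitochondrial morphology and transport).  The
WldS WD lag (400 min) encodes the classic axon-protective delay of
injury-induced fragmentation; it was not measured in this system.

Standard deviations are derived from published mean ± s.e.m. and group
sizes (sd = sem·√n), e.g. WT WD lag 129.1 ± 10.0 s.e.m. at n = 11 → sd 33.2
min.

### Published-density caveat

The printed mitochondrial density ("226.2 per μm") is dimensionally
implausible; profiles store density per 100 μm (WT 22.6, aSyn 30.2 —
reading the printed numbers as per-mm counts, giving a plausible ~4.4 μm
spacing).  Density is only ever compared directionally (aSyn > WT), never
as an absolute target.

## Transport model and generator

Motility is a latent per-mitochondrion Bernoulli label (WT motile fraction
0.274).  Motile organelles follow an alternating run/pause renewal process
with exponential (memoryless) dwell times, started in its stationary
distribution so the expected fraction of time paused equals the profile
target (WT 0.4125, from the published time-budget: 36.44% anterograde,
41.25% paused, remainder retrograde).  Each run draws its direction
(retrograde with probability 0.3797 for WT, the retrograde share of moving
time) and a speed from a normal distribution truncated below at 0.15 μm/s —
comfortably above the 0.1 μm/s pause threshold, so generated runs are real
runs — with the truncated-normal location solved numerically so that the
post-truncation mean equals the published mean run speed (WT anterograde
0.56 μm/s).

Mitochondria **reflect** at the ends of the 50-μm segment.  Hard clipping
(parking at the boundary) would convert run time into apparent pause time
and corrupt the dwell statistics; reflection keeps positions inside the
segment while preserving run/pause structure.  The cost is that direction
labels flip at the walls, which slightly mixes the anterograde/retrograde
split (and, with the net anterograde drift of the WT parameters,
concentrates movers near the distal end late in a movie); time-paused and
run-speed statistics are unaffected.

Movies are rendered as 8-bit stacks at 0.2 μm/px with a 0.3-μm Gaussian
PSF (typical confocal 40×/3×-zoom scale; the study reports none), 1 Hz for
6 min.  Spot amplitudes are drawn around 110 (clipped 80–140) so that even
two coincident mitochondria stay below the 8-bit ceiling — a saturated
flat-top blob has no usable peak for the tracker.  Stationary organelles
jitter by < 0.5 px.  Initial positions use a 1.2-μm hard-core exclusion
(organelles are discrete ~1-μm objects).

## Kymographs and tracking

Kymographs resample the traced axon at one-pixel arc-length bins and take
the **maximum** over a ±3 px band normal to the trace (maximum rather than
mean preserves punctate signals at low SNR).  Time is the row axis, the
proximal (cell-body) end is column 0, so anterograde = increasing column.

Track extraction decomposes the kymograph into static and moving parts.
The per-column temporal median captures stationary ridges, which become
constant-position tracks directly; movers are detected in the
static-subtracted residual as per-row peaks above half the Otsu threshold
(rows are zero-padded so boundary maxima are found; peaks closer than
0.8 μm are merged).  Greedy nearest-neighbour linking with
constant-velocity prediction uses a 1.5 μm per-frame jump limit (≈3× the
fastest published run speed) growing sub-linearly (√gap) across missed
frames, tolerates 2-frame gaps (linearly interpolated), lets an
established track share a detection claimed by another track when their
ridges merge (flagged identity-uncertain), and suppresses track births
within 1 μm of an existing track (in a closed segment, a detection there is
a subtraction shadow).  A final stitching pass merges fragments that abut
in time and space or overlap at nearly the same positions — movers that
pause on top of a static ridge can drop out of the residual for tens of
frames and must be re-joined.  Tracks with fewer than 10 frames (or fewer
than 8 real detections) are discarded; moving tracks that never leave a
0.5-μm neighbourhood of a static ridge are sub-pixel flicker and dropped.
Two movers crossing may swap identities; all downstream statistics are
identity-insensitive.

## Run/pause segmentation and transport statistics

Frame velocity is the smaller-magnitude of the backward and forward
one-step differences (one-sided at track ends).  Unlike a moving-average /
centred-difference estimate, this assigns a frame to a pause as soon as
either adjacent interval is still, so run→pause transitions do not bleed
run velocity into pause frames.  Frames with |v| < 0.1 μm/s are paused
(the motility speed threshold doubles as the pause cutoff; the study
defines no separate one).  Maximal constant-sign excursions form runs;
excursions displacing ≤ 0.3 μm (one detection bin) are quantization
flicker and are folded back into the pause.  Run speed is the
least-squares slope of position vs time over the run.

A mitochondrion is **motile** iff a single run carries it ≥ 2 μm at
≥ 0.1 μm/s — per run, not cumulative, so jitter cannot qualify.  Time
fractions are computed per motile mitochondrion from continuous-time state
durations, with each run↔pause boundary refined to the intersection of the
run's fitted line with the pause position (whole-frame counting would
overstate pause time by the conservative boundary labeling), then averaged
across mitochondria (each organelle weighted equally, matching the
published per-mitochondrion n).  Percent distance retrograde is the
per-mitochondrion ratio of summed |retrograde run displacements| to all
run displacements, averaged the same way; whether the study pooled or
averaged per mitochondrion is not stated, and per-mitochondrion averaging
was chosen.  Mean run speeds average per-mitochondrion means of
uninterrupted runs.

Validated operating point: recovery experiments simulate movies with 2
mitochondria per 50-μm segment.  At this sparse labeling density the
tracker's count errors are negligible (at ≥ 5 per segment, movers tangling
near the segment ends inflate the motile track count by a few percent).
With 1000 mitochondria the pipeline recovers WT percent motile to
27.7 ± 1.4 (target 27.4), time paused to ≈ 43 (target 41.25; the residual
+2 points is the irreducible frame-quantization of state boundaries at
1 Hz), and anterograde run speed to ≈ 0.545 (target 0.56).

## Morphology

The generator lays ellipses along a straight axon with a Poisson count
(density × length/100), hard-core gap-allocated placement (never biased
against long organelles), aspect ratios from a shifted log-normal whose
mixture mean equals the profile mean exactly (a `swollen_fraction` of
organelles are spheres with a 1.6× minor axis), and area-sampled rendering
(4× supersampling) before PSF blur and noise.

Segmentation thresholds with Otsu floored at background + 5 robust σ
(Otsu alone collapses into the noise mode when objects cover a small image
fraction), labels 8-connected components and discards those under 4 px.
With the PSF width known, each component's length and width come from a
Levenberg–Marquardt fit of a PSF-blurred uniform-ellipse model (centre,
log-semi-axes, orientation, amplitude) to its local patch: at these scales
the PSF contributes as much apparent width as the organelle itself, and a
parametric fit is the only well-conditioned deconvolution from one noisy
image (binary-mask moments compress a true 2:1 ratio to ~1.4; direct
moment deconvolution is catastrophically noise-sensitive because the minor
axis variance is smaller than σ²_PSF).  The model is rendered by
supersampling, so the fitter uses finite-difference steps larger than the
rendering granularity.  Pixels belonging to other components (dilated by
the PSF extent) are excluded from the residuals — forcing the model to
match "background" there would both shrink the organelle (its own blur
skirt lives there) and elongate it toward the neighbour's leaked
intensity.  Because the ratio's support is one-sided (≥ 1), noise alone
elongates a sphere's best fit; a near-circular ellipse fit is therefore
tested against a nested circle model (F-test at α = 0.05) and reported as
ratio 1 unless the elongation is supported.  Known limitation: mildly
elongated objects (ratio < 1.5) sit near a circularly symmetric saddle and
are read low by up to ~15% of their value at this optical scale; strong
elongations recover within a few percent, and the recovered WT mean ratio
carries a residual bias of roughly +0.1 (within the published standard
error band).

Density is reported per 100 μm; ratio histograms use right-open 0.25-wide
bins from 1.0 (bin width is not published).

## Axonopathy staging

Stages: 1 smooth/continuous, 2 mild beading, 3 severe beading or large
varicosities, 4 partial fragmentation (gaps), 5 complete degeneration or
soma death.  The original scoring rubric is not available in detail, so it
is operationalized with explicit, configurable thresholds
(`StagingThresholds`), checked from most to least severe (highest stage
wins): soma death or > 90% of length lost → 5; below-background gap
fraction ≥ 0.1 → 4; bead density > 10 per 100 μm or any varicosity wider
than 3 μm at half prominence → 3; any bead → 2; profile CV ≤ 0.3 → 1 (an
irregular but unbroken profile falls back to 2).  Beads are local maxima
reaching 2× the rolling median (20-μm window — wider than a varicosity's
footprint, which would otherwise raise its own baseline); varicosity
widths are measured on a 1-μm-smoothed profile so a bead riding a swelling
does not mask it.  "Above background" means above a fixed fraction (0.25)
of the 99th-percentile intensity, which makes staging invariant to
positive intensity scaling.  The stage-3 vs stage-4 boundary favours
fragmentation gaps for stage 4.

On noise-free generated profiles the round trip (generate stage k → score)
is exact, 100/100 across stages and seeds.

## Cohorts and survival

`simulate_cohort` evolves each cell's stage by the per-day monotone Markov
matrix; each initial cell survives 2→3 dpf with the profile probability,
dead cells are recorded at stage 5, and extra cells newly express the
reporter with a per-initial-cell probability (so 3-dpf counts can exceed
2-dpf counts — WT survival is 102.9% on average).  Percent survival is
100 × (3-dpf count, including new cells) / (2-dpf count).
`death_given_stage5` is retained as a consistency annotation (the observed
fraction of stage-5 axons whose soma died); death is driven by the
survival probability, not drawn a second time.

## Wallerian degeneration timing

True lag (transection → fragmentation) and clearance intervals are drawn
from zero-truncated normals; fragmentation is synchronous (the fragment
count jumps from 1 to its maximum within one 30-min sampling interval) and
debris then declines linearly over the clearance interval.  Measured lag
is the first frame with ≥ 2 fragments, so it is grid-quantized upward with
a +Δ/2 mean bias that `bias_corrected_mean` removes when averaging
replicates; clearance is the difference of two quantized times, whose
half-interval biases cancel (no correction), though the 5%-debris endpoint
reads ~0.05·C early.  Censoring (no fragmentation, or debris never
cleared) is reported, never imputed.  `onset_ordering` reports whether
stage ≥ 2 swelling and stage ≥ 4 fragmentation precede soma death in
longitudinal series; in the aSyn degeneration generator swelling leads
death by ~4 h while overt fragmentation follows it, matching the
uninjured-axon phenomenology.

## Statistics

Two-group comparisons use the unpaired pooled-variance (Student) t-test
(the classical default of the era; Welch is a switch), multi-group
comparisons one-way ANOVA, and post-hoc pairwise testing the Newman–Keuls
stepwise studentized-range procedure: groups ordered by mean, the pair
spanning r ordered means tested against q(α; r, df_error), with every
comparison interior to a non-significant stretch declared non-significant
untested.  Studentized-range quantiles are computed numerically
(`scipy.stats.studentized_range`), not from printed tables.  For two
groups the procedure reduces exactly to the t-test (q² = 2t²).

A note on power: with group sds reconstructed from the published
sem·√n, the WT-vs-aSyn WD lag comparison at n = 11/15 has ≈ 15% power, so
simulated replicates reproduce the published non-significant result in
≈ 85% of seeds.

## What the generator does not emulate

Real arbors are curved and branch; axons drift during acquisition;
photobleaching dims late frames; mitochondria enter and leave an imaged
segment (here they reflect); stage phenotypes vary continuously rather
than by rubric.  Passing recovery tests therefore demonstrates that the
measurement chain is unbiased under the stated acquisition model, not that
it is robust to every property of in-vivo data.

## Problem sizes

Recovery experiments use 1000 mitochondria (500 movies × 2) for
transport, ≥ 600 segmented organelles for morphology, 500–600 replicates
for WD timing, and 100 seeds for the null-replication rate; exact staging
and survival arithmetic run on the published distributions directly.
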