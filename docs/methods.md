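# Methods

This note documents the analysis model, the synthetic-data generator, the
statistical procedures, and the numerical and design choices behind
`flyconform`, in enough detail to reimplement or audit any step.

## Input model and conventions

The atomic input is a `GroupRecording`: per-individual 2D positions at a
fixed frame interval (default 0.5 s) in a circular arena (default 140 mm
diameter), with species/strain labels per individual and a group type
(`single`: one species, 24 individuals by convention; `mixed`: two species in
equal numbers, 12+12). Coordinates are millimetres with origin at the arena
center; frame indices are 0-based; time windows are half-open `[start, end)`.
Recordings conventionally span 60 minutes of which the final 30 are analyzed
(`clip_to_analysis_window`), mirroring a protocol in which the first half of
a recording is an acclimation period after handling. Missing frames are an
error, never interpolated: a gap means the tracker lost identity, and any
imputation would silently distort speeds and cues. Trajectory files are
neutral long-format TSV/CSV; floats are written with the shortest
representation that round-trips `float64` exactly, so write→read is the
identity on coordinates.

## Kinematics

Speed at frame *t* is the displacement from *t* to *t*+1 divided by the
frame interval; the final frame repeats the previous value so the speed
series stays frame-aligned with the cue series. Heading is the direction of
the same displacement. When the displacement magnitude is at or below
`stationary_epsilon_mm` (default 1e-6 mm, i.e. only exact holds) the last
defined heading is carried forward; frames before the first movement are
backfilled from it, and an individual that never moves gets heading 0. A
tracker-supplied heading column can be used instead
(`heading_source="file"`), but displacement heading is the default because it
is reproducible from coordinates alone and the orientation convention of
stationary flies differs between trackers.

## Visual cue

For focal *f* at frame *t*:

cue_f(t) = Σ over others *i* in the forward half-plane of
speed_i(t) × 2·arctan(w / (2·d_fi(t)))

* The **forward sector** is the closed half-plane: the neighbor is included
  iff the dot product of the focal heading with the focal→neighbor vector is
  ≥ 0. Inclusivity at exactly 90° makes the sector exactly 180°.
* The **projected width** *w* is the fixed 3.0 mm major axis of the ellipse
  body model for every neighbor regardless of its orientation; the 1.5 mm
  minor axis is stored but unused in the cue. A per-neighbor
  orientation-dependent projection would change the cue by at most a factor
  of 2 per term while requiring reliable neighbor orientations; the fixed
  width keeps the cue a function of positions and speeds only.
* **Distance clamp**: pair distances below 0.75 mm (half the minor axis,
  `distance_clamp_mm`) are clamped before the angular term. Tracking jitter
  can place two detections arbitrarily close; without the clamp a single
  frame could dominate an individual's whole cue series. `angular_size`
  itself never raises: non-positive distances are floored at 1e-12 mm, so
  the term is bounded by π.
* The cue is additive in neighbors, non-negative, invariant under rigid
  motions of the whole configuration, and strictly increasing in any
  in-sector neighbor's speed — these properties are enforced by tests
  against an independently coded pairwise-loop oracle.

**Transform.** The regression operates on log cues standardized within
species: zero observations are replaced by the minimum non-zero cue of the
standardization stratum, then the natural log is taken, then the stratum is
z-scored (population sd) over all of its individuals × frames. The default
stratum is species × group-type (`standardize_pool="stratum"`); pooling both
group types per species is available (`"species"`). Per-stratum
standardization is the stricter default because single- and mixed-group
recordings can differ systematically in overall activity, which would
otherwise leak a group-type offset into every individual's cue.
An all-zero stratum is an error (the offset is undefined), as is a
zero-variance stratum.

## Locomotion events

A frame is *walking* iff speed ≥ `walk_threshold_mm_s` (default 2.0 mm/s);
runs shorter than `min_bout_frames` (default 1, i.e. no smoothing) are then
absorbed into the preceding state in a single left-to-right pass. The first
run is exempt (there is nothing to absorb it into), absorption merges runs,
and later runs are judged against the already-merged sequence, which makes
the pass deterministic; `classify_states` is idempotent on its own output.
Both parameters are config-exposed and echoed into all outputs; the defaults
are declared conventions for 0.5 s data rather than values derived here, and
the pipeline's qualitative contracts are required by tests to hold across a
range of thresholds.

Event labels on top of the binary states: **walk** = stationary frame
directly followed by a walking frame; **stop** = walking frame directly
followed by a stationary frame; remaining walking frames are **walking**,
remaining stationary frames **stay**. The final frame has no successor and
is never *walk* or *stop*. The labels partition frames; the number of *walk*
(*stop*) frames equals the number of onsets (offsets), and they differ by at
most 1 per individual.

## Statistics

The statistical unit throughout is the individual: per-frame series are
summarized to per-individual means before any test.

* **Event contrast**: for a pair of event types, the statistic is the mean
  over individuals of the difference of their per-event mean transformed
  cues, restricted to individuals observed in both. The null flips the sign
  of each individual's difference independently (exchangeable under the
  no-difference null because the pairing is within-individual); p-values use
  the add-one estimator (1+extreme)/(n_perm+1), two-sided; Bonferroni
  multiplies by the number of contrasts in the family (default 4: stay→walk,
  walk→walking, walking→stop, stop→stay), capped at 1.
* **Sensitivity**: per individual, OLS of speed[t+lag] on z-cue[t]
  (`lag_frames` default 1 = 0.5 s; lag 0 supported). Slope units: mm/s per
  sd of cue. Differences among species and between group types are tested
  with one-way permutation F-tests on the individual slopes (label
  reshuffling, add-one p).
* **Species-level conformity**: each strain observed in mixed groups is
  baselined against the same (species, strain)'s single-group mean —
  unmatched strains are an error, not silently pooled. The default rate is
  the signed relative change (mixed − single)/single so that 0 means no
  change; a ratio variant is available. Strain rates aggregate to species
  by unweighted mean.
* **Group-level conformity**: Δ_single = |mean_A − mean_B| over single-group
  individuals, Δ_mixed likewise; reported with their difference (reduction)
  and ratio. Convergence is tested by permuting single/mixed labels within
  each species and asking how often the permuted reduction reaches the
  observed one.

Permutation analogues were chosen over the mixed-model machinery
(Tweedie/gamma GLMMs, Tukey post-hoc) that a full study would use: they are
exactly reproducible from a seed, assumption-light at these sample sizes,
and self-contained. The per-individual tables (`mean_speeds.tsv`,
`sensitivity.tsv`, `event_summary.tsv`, with strain and replicate
identifiers) are exported precisely so that external mixed-model analyses
remain possible.

## Synthetic arena generator

Each agent is a two-state Markov walker coupled to the visual cue:

* stationary → walking with per-frame probability
  `logistic(logit(base_walk_rate) + coupling_beta · z)`,
* walking → stationary with probability
  `logistic(logit(base_stop_rate) + stop_coupling · z)`,

where *z* is the agent's standardized cue this frame, computed online with
exactly the analysis-side cue model. The logistic link keeps probabilities
valid at arbitrarily extreme cues. `coupling_beta` is the ground-truth
conformity; `stop_coupling` (default 0) makes agents settle where others are
active. Walking agents move along their heading at a per-frame lognormal
speed with mean `walk_speed_mu_mm_s` (log-scale sd `walk_speed_sigma`,
default 0.3) and Gaussian heading noise `turn_sd_rad` per frame.

**Standardization constants.** The (offset, mean, sd) used for *z* are
calibrated per species from a zero-coupling single-species run with the same
speed parameters, group size and arena, under a fixed internal seed, and
cached. Calibrating at β = 0 avoids circularity between the online
standardization and the behavior it drives. Using *species-fixed* constants
(rather than re-calibrating per composition) is essential for the science:
it makes the behavioral response depend on the absolute cue level, so an
agent surrounded by faster heterospecifics sees z > 0 and raises its
activity — the mechanism behind mixed-group convergence. A
composition-matched recalibration would define away the very signal the
pipeline measures.

**Defaults.** `base_walk_rate = 0.12`, `base_stop_rate = 0.36` per 0.5 s
frame give a baseline walking fraction of 0.25 with short walking bursts
(mean 1.4 s) between longer pauses (mean 4.2 s), and `turn_sd_rad = 1.0`
gives strongly tortuous paths — both at the fast-switching end of what arena
flies do at 0.5 s resolution. These defaults are deliberate: the spurious
cue–state correlation that confined motion induces at β = 0 (below) scales
with state persistence (through the factor 1 − p_walk − p_stop) and with
heading persistence, and at these values the zero-coupling null is clean at
the resolution of the validation suite. The default species panel spans
baseline mean speeds 1, 2, 4, 10 mm/s (`walk_speed_mu` 4–40 mm/s),
mirroring a ~10× interspecific activity range; the intermediate 4 mm/s
species is the host with the strongest coupling (β = 1.2) and the fastest is
a weakly coupled influencer (β = 0.2), the others β = 1.0.

**Stationary micro-jitter.** The analysis derives heading from displacement,
so a perfectly frozen agent's measured heading would be the *incoming*
direction of the step on which it stopped, while walking agents show their
*outgoing* direction. Near a wall these two distributions necessarily differ
(arriving steps point outward, departing steps are deflected inward), which
correlates the forward-sector cue with the behavioral state even at β = 0
and would bias both the null sensitivity slope and the walk-vs-stay
contrast. Stationary agents therefore express a 0.05 mm per-frame
micro-jitter — far below the 2 mm/s walking threshold, of the order of real
tracking noise and grooming/pivoting movements — whose direction follows the
same per-frame heading law as a walking step (turn noise plus wall
deflection of the full-length step the agent would have taken). With
identical heading laws in both states, the measured cue is independent of
the walk/stay state at zero coupling, and the zero-coupling null is null by
construction rather than by cancellation.

**Boundary.** Wall handling is edge-following: an agent whose straight step
would exit walks to the wall and slides the remaining step length along it
(in the direction of its tangential motion component), preserving step
length. This matches real fly behavior at arena walls better than specular
bouncing, and it guarantees wall contacts never shorten a step below the
walking threshold (a mirror reflection can fold a step back on itself,
producing phantom stop/walk events at the wall with systematically biased
cues). The stored heading after any step is the realized displacement
direction, keeping the simulator's internal heading aligned with what the
analysis will measure.

**Initialization and burn-in.** Agents start clustered near the center
(single species: uniform disk of 0.28 R; mixed: two clusters at ±0.2 R on
the y-axis, so initial position encodes species as in real mixed trials),
with states drawn from the zero-coupling stationary distribution. The first
`burn_in_frames` (default 600 = 5 min) are simulated and discarded,
mirroring the acclimation period of the real protocol: during dispersal from
the center an agent's cumulative walking time correlates with its distance
from the center, which contaminates cue–behavior statistics. Returned
recordings represent the stationarized regime and use an analysis window
starting at 0. Identical parameters and seed give bit-identical recordings.

**What the generator does not emulate**: olfactory and acoustic cues,
collisions and physical contact, occlusion of the visual field, persistent
wall-hugging and thigmotaxis beyond the slide rule, post-anesthesia recovery
dynamics, sex differences, and real tracker failure modes (identity swaps,
gaps). Passing validation on this generator shows the pipeline recovers
conformity parameters when the data-generating process matches the cue model
it assumes; it does not show the visual cue is the true channel in any real
dataset.

## Validation suite and problem sizes

`make_validation_suite` writes the fixed panel (4 species in single groups +
3 host-centered mixed pairings, 2 pseudo-strains × 3 replicates, with
manifest, per-file parameters, seeds and SHA-256 checksums). Validation and
acceptance runs use desk-scale problem sizes chosen to keep the whole suite
in minutes on one CPU: 24-agent groups, 15-minute (1800-frame) windows for
effect-recovery checks, 30-minute (3600-frame) windows and 200 seeds for the
null-calibration check, and 20-seed replicate panels for the qualitative
patterns (cue rise into walk onsets, slope rank order across β ∈ {0, 0.5, 1,
2}, convergence of a 1 vs 4 mm/s pair under mutual β = 1, host/influencer
asymmetry at β = 1.2 vs 0.2).

## Numerical choices and degenerate inputs

* Sector boundary inclusive (dot ≥ 0); coincident pairs fall in-sector with
  clamped distance rather than erroring.
* Speed/heading at the last frame carry the previous value, keeping all
  per-frame series aligned and equal-length.
* Zero-offset, log, and z-score use population (ddof = 0) moments; the
  offset is the stratum minimum *non-zero* value, applied only to zeros.
* Permutation p-values always use the add-one estimator and an explicit
  seed; every output table echoes the full analysis configuration in a
  header comment block (filesystem paths excluded, so identical analyses are
  byte-identical wherever they run).
* Tabular floats are written at full round-trip precision for trajectories
  and `%.10g` for derived tables.
* Degenerate inputs error loudly with the offending individual/frame named:
  missing frames, non-finite coordinates, species counts violating the group
  type, all-zero cue strata, zero-variance regressors, unmatched strain
  baselines, sub-minimum simulation lengths.

## Known limitations

* The cue model ignores occlusion and perspective; apparent size uses a
  fixed projected width.
* Event statistics at the default `min_bout_frames = 1` count every
  threshold crossing; noisy real speed series may warrant a larger minimum
  bout and the absorption rule is only one of several defensible smoothing
  conventions.
* The permutation convergence test conditions on the observed group
  composition and does not model replicate- or arena-level random effects;
  for designs with many strains and replicates, export the individual-level
  tables and fit the appropriate mixed model externally.
* Sensitivity slopes are descriptive associations; with β = 0 the simulator
  shows they are unbiased under the generator's assumptions, but in real
  data common drivers (temperature shifts, disturbances) can induce
  cue–speed correlation that is not social in origin.
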