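# Methods

## Signal model and preprocessing

Each participant contributes two triaxial acceleration traces sampled at a
nominal 10 Hz, in units of g: a wrist-worn logger and a logger fixed in the
vehicle. Exports are plain delimited text with either numeric-seconds, a
single ISO-8601 datetime column, or separate date and time columns; all are
normalised to seconds since the first valid sample. Rows with unparseable
values or accelerations outside ±16 g (the device sanity bound) are dropped
and counted. A series must have at least two valid samples, strictly
increasing timestamps after sorting (duplicates are treated as a corrupt
timeline), and a median inter-sample interval within 20 % of the nominal
period. Gaps longer than 1 s can be split into contiguous blocks with
`split_on_gaps`; the reader itself always returns one series per file.

Device clocks are assumed synchronised up to a single constant offset
(default 0 s) applied to the wrist clock. `align_pair` crops both series to
their overlapping span (leniently, by half a sample period) and resamples
the wrist signal to the vehicle timestamps by nearest neighbour; vehicle
samples with no wrist neighbour within half a sample period are dropped and
counted. Alignment is idempotent.

## Drive detection

Vehicle axes follow the standard mounting: x fore/aft (longitudinal),
y left/right (lateral), z up/down — the z axis carries gravity, reading
about −1 g for a flat mounting. A configurable permutation accommodates
other mountings.

1. **Gravity detrend.** The per-axis median over the whole recording is
   subtracted. The median rather than the mean is used because drives are a
   minority of a naturalistic recording and event pulses are one-sided, so
   the median estimates the stationary (gravity) baseline robustly.
2. **Envelope.** The amplitude envelope of the longitudinal axis is the
   modulus of its analytic signal (FFT-based Hilbert transform), smoothed by
   a centred moving average of width `envelope_smooth_window_s` (default
   5 s). The raw modulus of a broadband signal is too jagged for run
   detection; the window sets the time resolution of segment boundaries.
3. **Runs.** Maximal runs with envelope above
   `activity_envelope_threshold_g` (default 0.03 g) are candidate drives;
   runs separated by gaps ≤ `merge_gap_s` (default 30 s, e.g. a stop at
   traffic lights) are merged, and merged runs shorter than
   `min_drive_duration_s` (default 60 s) are discarded. The 0.03 g default
   separates parked-vehicle sensor noise (≈ 0.002 g RMS) from sustained
   driving activity; it is a deployment tunable, not a claim about any
   particular vehicle.
4. **Event criteria.** For each candidate, the peak longitudinal
   acceleration (max +x), peak deceleration (max −x) and peak absolute
   lateral acceleration (max |y|) are computed on the detrended signal. A
   segment is retained as active driving iff any peak meets its criterion:
   acceleration ≥ 0.35 g, deceleration ≥ 0.45 g, or lateral ≥ 0.5 g (OR of
   the three). The criteria sentence in the source literature admits a
   second reading — keep every active period and treat the events as
   annotations — which is available via `retain_all_active`. Event scoring
   never moves segment boundaries, and raising any threshold can only
   shrink the retained set.

Wrist sub-series are then extracted over each retained segment of the
aligned pair.

## Movement volume

For each retained drive, the wrist (and, independently, vehicle) samples
form a point cloud in (x, y, z) acceleration space. Each cloud is trimmed
per axis to its 1st–99th centiles (linear interpolation between order
statistics; a point is kept only if all three coordinates are inside their
axis windows), removing occasional extreme artefacts. The trim is applied
per drive; the grouping level is a design choice, as is trimming per axis
rather than by a joint criterion.

The movement volume is the volume of the convex hull of the trimmed cloud
(Qhull), in g³. Gravity is deliberately **not** removed before hull
computation: the hull is taken on raw trimmed accelerations for both
devices, so a stationary vehicle cloud is a small blob near (0, 0, −1).
Clouds with fewer than four points, or affinely degenerate ones (smallest
singular value of the centred cloud ≤ 1e−12 relative to the largest), get
volume 0 and a `degenerate` flag rather than an error, so stationary
periods remain representable.

Per participant, the default aggregation is the hull of all trimmed drive
clouds pooled — the overall envelope explored across every retained drive,
matching the notion of one movement volume per participant. The arithmetic
mean of per-drive volumes (`mean_per_drive`) is available where a
per-drive-normalised quantity is preferred; for a single drive the two
coincide. `hull_evolution` provides the within-drive view: cumulative hull
volumes over n equal spans (quarters by default), which are non-decreasing
and terminate at the full-drive volume. Spans are equal in time when
timestamps are supplied and equal in point count otherwise; on a uniform
grid the two coincide.

## Cohort statistics

Quartiles use linear interpolation between order statistics; SD is the
sample (n−1) estimate; skewness is the adjusted Fisher–Pearson sample
coefficient; Shapiro–Wilk is valid for 4 ≤ n ≤ 5000. The outlier rule is
the Tukey **upper** fence only, Q3 + 1.5·IQR, flagging atypically *high*
movement (strictly greater than the fence); low movement is not an outlier
condition here. Outlier percentages are reported to 2 decimal places.
`log10_compare` produces raw and log₁₀ summaries side by side and asserts
that the participant ranking is unchanged (log₁₀ is strictly monotone);
reports default to raw units, which are the clinically interpretable ones.
Constant cohorts are degenerate for the normality diagnostics and report
skewness 0 with NaN Shapiro–Wilk values.

## Synthetic cohort generator

The generator emulates exactly the signal features the pipeline consumes,
not vehicle dynamics or biomechanics:

- **Vehicle channel.** Gravity (−1 g on z by default) plus a 0.002 g
  sensor-noise floor when stationary. Each scripted drive adds: a
  longitudinal "maneuvering" sinusoid (amplitude 0.05–0.10 g, 0.1–0.3 Hz)
  that keeps the Hilbert envelope above the activity threshold for the
  whole drive — with road vibration alone (default SD 0.01 g) the smoothed
  envelope would sit below 0.03 g and drives would be undetectable by
  design; band-limited road vibration (white noise band-passed to
  1–4.5 Hz) on all axes; a smaller lateral sway; and half-sine event pulses
  (1–3 s wide) of scripted magnitude, drawn uniformly on 0.20–0.60 g so
  both sub- and supra-criterion events occur. Pulses are kept ≥ 20 s inside
  the drive: the analytic-signal modulus of an isolated pulse leaks ~1/t
  beyond it, and an edge pulse would smear the detected boundary well past
  the scripted one.
- **Wrist channel.** A fixed random rotation of the vehicle-induced motion
  (the arm rides in the same vehicle, the device sits at an arbitrary
  attitude), gravity re-oriented by a slow random-walk attitude drift
  (default 0.005 rad·s^−1/2), and voluntary half-sine bursts in random 3-D
  directions during drives (default 8/min, 0.5–2 s), plus one
  steering-correlated burst per scripted lateral event. The per-participant
  burst amplitude is log-normal (median 0.5 g, σ_log 0.8), which is what
  makes the cohort of wrist volumes right-skewed; with amplitude 0 and no
  drift the wrist cloud is an exact rigid rotation of the vehicle cloud and
  the hull volumes coincide.
- **Cohort scale.** Defaults are an 89-participant cohort of 45-minute
  recordings with on average 3 drives of 90–240 s each — long enough that
  every stage (envelope, merging, minimum duration, event screening,
  trimming, hulls) operates as it would on day-scale data, while a full
  cohort run completes in well under a minute per stage. Each drive is
  guaranteed at least one clearly supra-criterion event
  (`guarantee_event_per_drive`), so every simulated participant has a
  defined movement volume; the guarantee requires a margin (maximum
  maneuvering amplitude + 5 vibration SDs) above the criterion because an
  event riding on the maneuvering signal can otherwise be cancelled back
  below threshold. Disable the guarantee to exercise the non-retained
  branch.

All randomness derives from `SimulationParams.seed` combined with a stable
CRC-32 hash of the participant id, so identical parameters give
bit-identical recordings and files; the cohort manifest stores file names
relative to its directory, making a generated cohort relocatable.

What passing tests on this generator do **not** show: robustness to real
GENEActiv-style artefacts (temperature drift, calibration error, device
re-orientation on the wrist strap, non-driving arm activity bleeding into
drive windows), driver-vs-passenger ambiguity, or realistic road and
traffic structure. Results on synthetic cohorts validate the pipeline's
mechanics and its distributional behaviour, not clinical validity.

## Numerical choices and degenerate inputs

- Hull degeneracy tolerance: 1e−12 on the relative smallest singular value;
  Qhull failures on near-degenerate clouds also map to volume 0.
- Envelope edge effects: the FFT-based analytic signal is circular, so
  envelope values within roughly one smoothing window of the recording ends
  are treated as unreliable in tests; detection of minute-scale runs is
  insensitive to them.
- Moving-average smoothing normalises by the in-window count, so constants
  are preserved at the edges.
- Nearest-neighbour alignment breaks distance ties toward the earlier
  sample.
- A segment is matched to scripted truth when the intervals overlap at all;
  matching is one-to-one in time order.
- `pct_outliers` is rounded to 2 decimals at the reporting boundary; all
  internal comparisons use full precision.

## Known limitations

- Hull volume grows with recording/drive count under pooled aggregation
  (hulls are monotone in points); comparisons across participants assume
  comparable observation effort, and `mean_per_drive` is the alternative
  when it is not.
- The convex hull is sensitive to single extreme excursions even after the
  centile trim; it is a descriptor of spatial extent, not of movement
  quantity or smoothness.
- No attempt is made to subtract vehicle-induced motion from the wrist
  signal; the vehicle volume is reported alongside as a reference instead.
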