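# Methods

This note documents the models and procedures implemented in `tagtrack`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Data model and conventions

Coordinates are WGS84 decimal degrees, longitude negative west of
Greenwich; all distances are great circles on a sphere of mean radius
6371.0 km. Timestamps are UTC, ISO-8601 in files, and hour bins are
clock-aligned half-open intervals [h, h+1). Depth is positive down
everywhere — sensor records, bathymetry and reference-field levels — so no
sign conversions occur inside the pipeline. Sensor depths in (−1, 0) m
are treated as surface noise and clipped to 0; deeper negative values are
rejected as corrupt.

The 90-s archival records are reduced to hourly observations before
geolocation: per hour, the **maximum** depth (the most constraining value
against the water column), the mean depth, and the mean temperature. The
choice of max-depth for the feasibility constraint and mean temperature at
mean depth for the thermal match is ours; the alternative (mean depth for
both) weakens the bathymetric constraint for a bottom-oriented fish.

Maturity is assigned by total length against L50 = 437 mm (L95 = 553 mm
is carried for reference); these are the published maturity lengths for
Channel pollack.

## Detection quality control

Each detection is scored on six criteria. Two are *hard*: a timestamp
before the fish's release, or outside the receiver's deployment window
(including unknown receivers), always invalidate. Four are *soft*:
isolation (no same-tag detection within ±24 h at any station), excess
velocity (implied speed to the nearest-in-time same-tag detection above
v_max), implausible distance from the release point (farther than
v_max × time since release), and low signal-to-noise ratio (< 6 dB when
reported). One soft flag marks a detection *suspect* (retained but
marked); two or more invalidate it. Defaults: isolation window 24 h,
v_max = 2.0 m/s (generous for a sustained speed of a slow-moving gadid),
SNR floor 6 dB; all configurable.

Velocity uses great-circle distance between station positions; a
consecutive pair at the same station has zero implied speed, and repeat
pings (zero distance, zero gap) are not speeding. Because removing an
invalid detection can change a survivor's neighbourhood flags, the
`qc_filter` convenience iterates score-and-drop to a fixed point, which
makes filtering idempotent by construction.

The behavioural metrics run on the filtered table (suspects included);
the geolocation model, whose acoustic term is a hard point constraint,
uses only fully-valid detections.

## Survival proxies

*Short term*: fish released inside a monitored bay pass two temporary
receivers placed in sequence on the way out. A fish detected at the inner
and subsequently the outer station — or detected anywhere else in the
network, having left unseen — is a survivor; a fish whose record is a
continuous stationary run at one temporary station is presumed dead;
anything else is unassessed.

*Long term*: a fish is a survivor if it was detected by the permanent
network (temporary stations excluded) and/or recaptured at least seven
days after release; otherwise its fate is unknown. Percentages are
rounded half-up to integers, matching the reporting convention of
telemetry studies.

*Stationary mortality*: a tag whose terminal run of detections is at a
single station with a median inter-detection gap at most twice the
nominal ping interval (180 s), sustained for at least seven days through
the end of its series, is flagged as a dead fish or shed tag lying within
receiver range. The numeric rule (2× ping interval, ≥ 7 days) is ours —
the behaviour it operationalises is "continuous detections at the average
ping frequency" — and both constants are arguments. Flagged terminal runs
are excluded from the residency analysis.

## Residency, effort, movement graphs

Consecutive same-station detections closer than a threshold (default
24 h) belong to one residency period; a single detection is a period of
duration zero. The threshold sensitivity sweep (1–24 h) is part of the
API because the period count depends on it by construction
(non-increasing in the threshold). Listening effort is the sum over
receivers of the (fractional) days their deployment overlaps each
calendar month; detection and distinct-individual counts are normalised
by it, overall and by maturity class. Movement graphs connect consecutive
distinct located events per fish (release, station-level detections,
recapture); edges carry the season of the later event (Winter = DJF,
Spring = MAM, Summer = JJA, Fall = SON) and the fish's maturity class,
weighted by the number of distinct individuals.

## Geolocation model

**State space.** Hourly position on a regular lat/lon grid with a boolean
sea mask. The time step of one hour matches the hourly reference fields.

**Movement.** Isotropic Gaussian kernel with standard deviation σ in
grid-cell units per √hour, truncated at 4σ and renormalised. At the
coast the kernel is masked and renormalised — the effective transition is
`T(i→j) = K(j−i)·sea(j)/Z(i)` — so probability is conserved
(reflecting-like behaviour), chosen over absorbing loss. σ is reported
both in cell units and in km·h⁻¹ᐟ² via the mean cell size.

**Depth emission.** A cell is fully feasible when its instantaneous water
column (bathymetry + sea-surface height) is at least the hour's maximum
recorded depth minus a slack σ_z (default 5 m); shallower cells receive a
Gaussian penalty on the shortfall. The constraint is one-sided: a fish
can always be shallower than the seabed.

**Temperature emission.** Unnormalised Gaussian in the difference between
the hour's mean recorded temperature and the reference temperature
interpolated linearly in depth to the hour's mean depth; cells whose
water column is shallower than that depth use their deepest available
level. σ_T defaults to 1.0 °C, absorbing both sensor error and
reference-field bias; neither sd is identified by the data, so both are
configuration, not estimates.

**Acoustic emission.** The detection range (~300–400 m) is much smaller
than a grid cell (~2 km), so the emission uses the *coverage fraction*
f(c) of each cell by the detection disk: a detection pins the state to
cells with positive coverage by every detecting receiver (weight ∝ the
product of fractions; an empty intersection between simultaneous
detections at distant stations is an infeasibility error); an hour
without detections weights each cell by Π(1 − f) over the receivers
active that hour — exactly zero for fully covered cells, mildly reduced
for partially covered ones — times a configurable non-detection value
(default 1) elsewhere. The hard-zero limit of this rule (range ≥ cell)
reproduces the classical indicator form; at sub-cell ranges the coverage
form is the probability-consistent discretisation, and simulation shows
the hard zero otherwise degrades the track when acoustic data are added.
Masking applies only to receivers deployed during that hour; an hour with
no active receivers is uninformative (uniform).

**Anchors.** The release position replaces the first likelihood slice
with a one-hot; a known recapture position multiplies the last slice. If
a final-hour detection sits in a different cell than the recapture point
(possible at cell resolution), the recapture — a direct observation —
takes precedence and replaces the slice, with a logged warning.

**Inference.** Standard forward–backward on the grid with per-step
normalisation accumulating the log marginal likelihood; convolutions
implement the kernel. σ is estimated by a bounded Brent search on the
forward log-likelihood (tolerance 10⁻³ cells); sigmas too small to bridge
consecutive constraints are treated as −∞ likelihood rather than errors
during the search. A flat or monotone profile triggers a warning and
returns the boundary value.

**Track outputs.** Mean track = probability-weighted centroid of sea-cell
centres per hour; mode track = argmax cell (ties break to the lowest
(lat, lon) index); positional spread = RMS distance from the mean in km.
Distance travelled is summed on the daily mean track by default, since
hourly posterior jitter inflates hourly sums; resolution is a flag.
Track sensitivity is the per-hour distance between the mean tracks
estimated with and without the acoustic component, summarised as mean
[min–max].

**Dead tags.** A run is expected to end at the presumed death time; the
caller truncates the sensor series there (a sustained near-surface record
identifies a floating tag). Post-mortem drift is not modelled.

## Synthetic data generator

The generator emulates a coastal double-tagging campaign with known
truth. Defaults describe a one-month study: a 45 × 45 grid of ~2 × 2 km
cells with a sinusoidal coastline on its eastern edge; bathymetry ramping
to 120 m offshore with a zonal channel; an M2 tide (amplitude 1.5 m,
period 12.42 h) with a small zonal phase lag; temperature on five levels
(0–100 m) with a 0.5 °C/degree zonal gradient, seasonal (2 °C) and diel
(0.3 °C) cycles and a 0.02 °C/m lapse. Twenty fish (60% double-tagged,
half of those recovered with a recapture position; half released inside a
two-temporary-station bay) follow Brownian walks of σ = 1 cell·h⁻¹ᐟ²
rejected off land. Hourly depth behaviour draws a water-column fraction
from Beta(5, 2) — seabed-biased, reflecting the bentho-demersal habit
that makes archival geolocation informative for gadids — and 90-s records
add Gaussian sensor noise (0.3 m, 0.1 °C). Receivers (eight permanent
along the coast plus the two temporary bay stations, 400 m hard-disk
range, open-protocol) log pings with exponential gaps of mean 180 s while
the fish is in range; false detections are injected per receiver as a
Poisson process (0.05 per receiver-day per tag) with near-threshold SNR
(3.5 ± 1.2 dB, against 20 ± 5 dB for true detections), labelled in the
truth output. Everything is reproducible bit-for-bit under a fixed seed.

What the generator does **not** emulate: reference-field bias (the
simulated fish lives in exactly the gridded environment, so emission
mis-specification is absent), within-hour movement, behavioural states,
receiver-range variability with sea state, and tag drift after death.
Passing validation therefore demonstrates internal consistency of the
estimator chain, not field accuracy against an imperfect ocean model.

## Validation experiments and problem sizes

The `tagtrack.validation` module (run by the test suite and
`scripts/acceptance.py`) uses deliberately small problem sizes so the
whole chain runs in minutes on one CPU:

- smoother vs. exhaustive path enumeration on 3×3/5-step and 4×4/3-step
  grids with a land cell (agreement to 10⁻¹⁰);
- posterior calibration (slices sum to 1 within 10⁻⁹, land mass exactly
  zero) on a six-day synthetic geolocation;
- σ recovery within ±20% (median over 20 seeds) on 200-step tracks with
  an informative Gaussian position-observation likelihood (sd 1 cell).
  This isolates the estimator. With depth/temperature emissions alone the
  likelihood constrains position only at the scale of isotherm/isobath
  bands and σ is weakly identified — estimates are then noisy and
  median-biased low (of order 20–30% in our experiments), a known
  limitation of diffusion estimation from band-like emissions that users
  should expect with real archival data too;
- acoustic information: median mean-track RMSE over 20 seeds does not
  increase when true detections are added, measured on a resident-fish
  scenario (σ = 0.6, 600 m range) in which every run actually contains
  detections;
- QC recovery on the default labelled scenario: ≥ 90% of injected false
  detections carry at least one flag, ≤ 5% of true detections are
  flagged, and the filter removes ≤ 5% of true detections (measured:
  ~98%, ~2%, 0%);
- residency periods equal a brute-force gap scan at every threshold from
  1 to 24 h, with the period count non-increasing;
- the track sensitivity of an undetected fish with no listening receivers
  and σ held fixed is exactly zero (the two likelihoods are identical).

The survival worked examples rebuild the published cohort structure from
its printed counts (35 bay releases with one presumed mortality; 83
tagged fish with 27 + 5 French and 3 UK long-term survivors) and push it
through the classifier, reproducing the printed 97% short-term and 42%
(46% France, 23% UK) long-term rates; the mean of the seven printed
per-fish track sensitivities (17.2 km) and the 2.0 km/day slowest-fish
rate are recomputed through the distance machinery.

## Known limitations

- σ is weakly identified from depth/temperature alone (above); per-fish
  σ estimates should be read as order-of-magnitude movement scales.
- The acoustic emission treats within-cell position as uniform each hour;
  temporally correlated near-receiver residence slightly over-counts
  non-detection evidence.
- Regular lat/lon grids only; no behavioural state-switching; no
  light-based or tidal-harmonic geolocation; no post-mortem drift model.
- The QC scheme is a graded re-design in the spirit of published
  detection-QC procedures, not a transcription of any specific scoring
  table; thresholds are explicit configuration.
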