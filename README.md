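# tagtrack

Combined acoustic-telemetry and archival-tag analysis for coastal fish
tracking, built around the double-tagging design used for pollack
(*Pollachius pollachius*) in the English Channel: fish carry an acoustic
transmitter (presence records at moored receivers) and, for the larger
individuals, a data storage tag (DST) logging depth and temperature every
90 s until the tag is recovered.

The package is aimed at movement ecologists who need to turn those two raw
data streams into quality-controlled detections, survival and residency
statistics, and reconstructed tracks:

- **acoustic QC** (`tagtrack.qc`) — graded quality control of detections
  against six criteria (release date, deployment window, isolation,
  velocity, release-distance plausibility, signal-to-noise ratio); hard
  flags always invalidate, one soft flag marks a detection suspect, two
  invalidate it.
- **telemetry metrics** (`tagtrack.metrics`) — short-term survival from a
  sequential two-temporary-station design, long-term survival from
  detections/recaptures at least a week after release, stationary-mortality
  flagging, residency periods with threshold sensitivity, monthly listening
  effort, and seasonal movement graphs by maturity class.
- **HMM geolocation** (`tagtrack.hmm`) — a gridded hidden Markov model for
  hourly positions. Emission likelihoods combine depth feasibility
  (bathymetry + tidal sea-surface height vs. the hour's maximum recorded
  depth), a Gaussian temperature match at the recorded depth, and acoustic
  presence/absence; movement is a Brownian kernel with diffusion
  coefficient σ (cells · h⁻¹ᐟ²) estimated by marginal-likelihood
  maximisation; forward–backward smoothing yields the posterior position
  distribution, from which mean/mode tracks, distances travelled and the
  track-sensitivity diagnostic (distance between tracks estimated with and
  without acoustic data) are derived.
- **synthetic data** (`tagtrack.simulate`) — a full synthetic study
  (environment, Brownian tracks, 90-s DST records, receiver network, true
  and injected-false detections) with ground truth, for testing and
  validation.
- **pipeline + CLI** (`tagtrack.pipeline`, `tagtrack` command) — one
  config-driven run: simulate → QC → metrics → geolocate → sensitivity →
  report, with a JSON manifest for reproducibility.

## The model

The sea is discretised on a regular lat/lon grid (~2 × 2 km). The fish's
hourly position `x_t` is a hidden state with

- movement model: `x_{t+1} | x_t ~ N(x_t, σ² I)`, discretised as a
  truncated Gaussian kernel, masked and renormalised at the coast;
- observation model per hour and cell `c`:
  `L_t(c) = L_depth · L_temp · L_acoustic`, where `L_depth` is 1 when
  `bathy(c) + ssh_t(c) ≥ zmax_t − σ_z` (Gaussian shortfall penalty
  otherwise), `L_temp = exp(−(T_tag − T_ref(c, z̄_t))²/2σ_T²)`, and the
  acoustic term pins detection hours to the detecting receiver's cell(s)
  (in proportion to the fraction of each cell covered by the detection
  disk) and down-weights covered cells in non-detection hours;
- anchors: the release position replaces the first slice; a known
  recapture position constrains the last.

Forward–backward smoothing gives `P(x_t | all data)` per hour; σ is
estimated by maximising the log marginal likelihood with a bounded scalar
search.

## Worked example

Run the full pipeline on a synthetic campaign (10 days, 8 fish):

```sh
cat > run.yaml <<EOF
scenario:
  duration_days: 10
  n_fish: 8
EOF
tagtrack run --config run.yaml --seed 7 --out runs/demo
```

which prints exactly, for this seed:

```
tagtrack run report
========================================

Detections: 185 raw, 164 retained after QC

Survival
  short_term [all]: 4/4 = 100%
  long_term [all]: 5/8 = 63%
  long_term [double_tagged]: 4/5 = 80%
  long_term [single_tagged]: 1/3 = 33%

Residency: 7 fish, mean 2.9 periods of mean duration 1.1 h

Geolocation: 2 recovered archival tags
  AT001: 36 km over 8 d, sigma 0.81 cells/sqrt(h) (1.62 km/sqrt(h)), sensitivity 0.2 [0.0-0.3] km
  AT002: 19 km over 8 d, sigma 0.49 cells/sqrt(h) (0.97 km/sqrt(h)), sensitivity 0.3 [0.0-0.8] km
```

Reading the geolocation lines: each recovered DST yields a reconstructed
track; `sigma` is the fitted Brownian step scale, the distance is the sum
of daily mean-track displacements, and `sensitivity mean [min–max]` is the
per-hour distance between the tracks estimated with and without the
acoustic detections — small values mean the archival data alone already
pin the track.

Individual stages are available as `tagtrack simulate|qc|survival|
residency|effort|graph|geolocate|sensitivity`; see `tagtrack --help`.

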