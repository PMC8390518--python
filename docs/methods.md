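# Methods

## The three-state kinetic model

A cellulase molecule is in solution, statically bound, or processively
moving. Landings enter the static state with probability `p_land_static`
(default 0.944) and the processive state otherwise. Exits are first order:

| state | total exit rate | routes |
|---|---|---|
| static | `k_off_static + k_processive` | unbind, start a run |
| processive | `k_off_processive + k_static` | unbind, stall |

Defaults (`SimConfig`): `k_off_static = 0.0106`, `k_processive = 0.00064`,
`k_off_processive = 0.0113`, `k_static = 0.0379` s⁻¹. Dwells are
exponential in the total exit rate; the exit route is drawn with
probability rate/total. `predict_observables` gives the closed-form
observables of the embedded chain (probability of ever moving, expected
visit counts, expected bound time per state); these are cross-checked
against Monte-Carlo sampling in the test suite.

## The synthetic-data generator

The generator emulates the imaging experiment: 1 frame/s, 1000 frames,
landings uniform over the first 500 s, isotropic Gaussian localization
noise of 1.5 nm SD per coordinate, optional shared stage drift, optional
jump events (Poisson in bound time, default 8×10⁻⁴ s⁻¹, radial distance
exponential with 48.6 nm scale truncated at the 100 nm re-association
search radius — the true jump-distance law is unknown; the exponential is
a stand-in). Processive motion is 1D along a fixed random heading per
binding event, a proxy for movement along a cellulose strand.

**Speeds.** Observed segment velocities are reported as mean ± SD
(3.24 ± 2.68 nm/s), which are sample moments of the *detected* population.
The generator therefore draws speeds from a truncated normal
parameterized by its **post-truncation** moments: the underlying
(μ, σ) are solved so that the distribution on [0.5 nm/s, ∞) has exactly
the configured mean and SD (`truncnorm_from_moments`). With the default
moments the solution is strongly left-censored (nearly a shifted
exponential) — parameterizing the untruncated normal instead would shift
the realized mean to ~4.0 nm/s and break the correspondence with the
observable.

**Run-length mode.** The printed velocity, segment duration and run
length means (3.24 nm/s, 20.3 s, 38.6 nm) are mutually inconsistent under
constant-speed segments, so the generator offers two motion modes. In
`duration` mode the processive dwell is exponential (run length
emergent); in `runlength` mode the run length is drawn as
10 nm + Exponential(28.6 nm) — i.e. the *detected* (>10 nm) run-length
distribution has mean 38.6 nm — and the dwell is length/speed.

**What the generator does not emulate.** Qdot blinking and bleaching,
enzyme crowding, cellulose fibril geometry, diffusive search states, and
any correlation between speed and run length. Passing recovery tests on
this synthetic data therefore validates the estimators under the model's
assumptions, not the model itself against real movies.

## Localization and drift correction

Spots are detected as non-maximum-suppressed local maxima
(`skimage.feature.peak_local_max`) and fitted with a symmetric 2D Gaussian
plus constant offset by bounded least squares; sub-pixel centers convert
to nm at 66.0 nm/pixel. Fits that fail to converge or return non-positive
amplitude are rejected with a reason. The default rendered photon budget
(16 000 photons/frame) was calibrated so the fitted localization SD
reproduces the ~1.5 nm tracking precision the downstream analysis
assumes; the Thompson-style bound `localization_precision_bound` provides
the reference scale. Greedy nearest-neighbour linking (deterministic
tie-break by spot index) tolerates `max_gap` missing frames; tracks
covering ≥99% of frames (optionally above an amplitude threshold — beads
far outshine single emitters) are flagged fiducial. Per-frame drift is
the mean fiducial displacement from frame 0, linearly interpolated across
fiducial gaps, and subtracted from every track; with noiseless fiducials
the cancellation is exact to machine precision.

## Trajectory segmentation

Classification runs on 5-point boxcar-smoothed positions (edges use
shrinking windows); jumps are detected on raw positions first, so
smoothing cannot dilute a two-frame displacement.

**Jumps.** A jump is a displacement >10 nm completed within ≤2 frames,
landing within 100 nm of the pre-jump anchor. Two guards make this
specific to genuine unbind–rebind events: the displacement is measured
between two-point position means (halving the noise contribution so
mid-run noise spikes at 2–3 nm/s rarely reach threshold), and both flanks
must be quasi-static (<7 nm over 4 frames), since a jump connects two
anchored positions. Consequences: the onset of a very fast run (>5 nm/s)
is not mistaken for a jump, and conversely a jump occurring *during*
processive motion (~4% of jumps at the default rates) is not detected. A
short (<5 s) fast burst in the first frames after landing is reported as
a landing jump — at 1 frame/s it is operationally indistinguishable from
a search jump. Detected jumps re-anchor all subsequent positions, so jump
displacement never enters segment displacement or run length, and every
jump terminates the current segment without ending the binding event.

**Changepoint scan.** A static segment holds while the smoothed position
stays within `static_radius` (10 nm) of its anchor. On crossing, the
excursion onset is back-tracked to the last frame within
`excursion_floor` (3 nm) of the anchor; if no frame returns to the floor
(the apparent anchor was shifted, e.g. by a sub-threshold jump) the
closest approach is used instead, and the excursion must reach the radius
within `static_radius / stall_speed_max` of its onset — a crossing that
takes longer is a noise spike, not motion. The candidate run closes when
a trailing `close_window` (10 s) shows net displacement below
`close_radius` (4 nm); if the track ends mid-run, a terminal stall of at
least 5 s is certified from the end-of-track tail (all tail points near
the final position and fitted tail speed < `stall_speed_max`
= 0.6 nm/s). The candidate becomes a processive segment only if it spans
≥10 nm over ≥5 s; otherwise its time is absorbed into the surrounding
static period. Static intervals shorter than 5 s between two processive
runs are below the stall resolution and merge into one run; a
sub-threshold *leading* static is indistinguishable from onset fuzz of an
immediate processive landing and is likewise absorbed.

The scan parameters (`close_window`, `close_radius`, `excursion_floor`,
`stall_speed_max`) are noise-scaled: with 1.5 nm localization noise and
5-point smoothing, static net displacement over a 10 s window is ~1.3 nm
(Rayleigh), so 4 nm separates stasis from sustained motion down to
~0.6 nm/s. A scan-window choice of 6–12 s changes the cohort statistics
by well under their sampling error.

**Resolution limits (also encoded in `expected_from_truth`, the
oracle used to score the detector against ground truth):** processive
excursions below 10 nm, shorter than 5 s, or slower than ~0.6 nm/s are
operationally static; static interludes shorter than `close_window` merge
into the surrounding run. These limits are the reason the
static→processive rate constant is recovered with a systematic ~15–20%
deficit relative to the generative value: the analysis (like the
experiment it mirrors) cannot count runs it cannot see. Run lengths of
detected segments sit a few percent above the generative truncated mean
because run length is independent of speed while detectability
(duration ≥5 s) removes short runs of fast movers.

**Estimators.** Per-segment velocity is raw-endpoint displacement over
the detected interval (smoothed endpoints are pulled inward by the boxcar
by ~0.6 × speed per side and would bias velocity low); run length is the
displacement between anchor-refined endpoints — the mean position of the
adjacent static segment where available — which removes the onset/stop
detection margins. A line-fit slope velocity is available via
`velocity_estimator="slope"`. A max-deviation static criterion is the
default; a positional-SD variant is available via
`static_criterion="sd"`.

**Filters.** Molecules bound <10 s (too short to classify), >510 s
(potential irreversibly adsorbed outliers) or landing after 500 s
(premature truncation by the movie end) are excluded, with per-rule
counts reported. Segments truncated by the movie end are marked censored
and excluded from dwell fits and branching counts, as are jump-terminated
segments (the jump interrupts the dwell without revealing the exit
route).

## Dwell-time fitting and rate derivation

Dwell samples are windowed — molecule-level binding durations to
[10, 510] s, segment dwells to [5, 310] s — and fitted with the MLE of an
exponential restricted to the window: with no upper edge this is the
memoryless shift `tau = mean − t_min`; with a finite window the MLE
solves `mean − t_min = tau − T/(expm1(T/tau))`, `T = t_max − t_min`.
The correction matters: simply discarding durations above 310 s would
bias an 89 s time constant low by ~11%. Observations above the window are
discarded, not right-censored, mirroring the exclusion rule; a censored
likelihood is deliberately out of scope. 95% CIs are percentile
bootstrap, 1000 iterations, resampling molecules (or segments), seeded.

The static time constant pools the static-molecule fit with the
static-segment fit as a count-weighted mean (`static_pooling="weighted"`,
with `molecules_only`/`segments_only` alternatives, since the exact
weighting used in the field is not standardised). Route rates are
branching fraction × exit rate, so the decomposition identities hold to
machine precision by construction. The static branching pools the
unbind-only exits of entirely static molecules with the segment exits of
processive molecules.

With the default weighted pooling of 89.0 s (n = 4136) and 85.9 s
(n = 1820) the pooled constant is 88.05 s and the static exit rate
0.01136 s⁻¹. Note that applying the pooled branching arithmetic to those
published counts gives a static→processive rate near 0.0013 s⁻¹, not the
0.00064 s⁻¹ carried by the generator defaults; the derivation behind the
published split is not fully reconstructible from the printed numbers, so
this package always derives route rates from its own counts and treats
the default pair purely as generator settings.

## Problem sizes and known limitations

Recovery tests and the acceptance script use 3000–6000 simulated
molecules per cohort — enough that binomial error on branching fractions
(~500 processive segments per cohort) is below the assertion tolerances —
and 200–500 replicates for estimator bias and bootstrap-coverage checks.

Quantities *not* reproducible from synthetic data at these scales, and
therefore reported but never asserted: the real-data population
percentages (89.9% static / 10.1% processive / 7.3% jumping), the 165.7 s
processive-molecule binding duration (our cohorts reproduce its order but
its fit window is not fully specified), and the instrument's 1.5 nm
stage-step precision (an input to the noise model, verified only as the
rendering/fitting round trip). For context on why static molecules cannot
be surface-diffusing: a particle with the ~2×10³ nm²/s diffusion
coefficient of an isolated cellulose-binding module would travel
`sqrt(4Dt)` ≈ 8.4×10² nm in a typical 89 s dwell
(`kinetics.diffusion_length`), yet static molecules stay within 10 nm.
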