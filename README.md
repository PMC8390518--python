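# cellodyn

Single-molecule tracking analysis of processive cellulases on cellulose.

Cellobiohydrolases such as *Trichoderma reesei* Cel7A degrade crystalline
cellulose by binding to a glucan chain and processively cleaving cellobiose
units, moving a few nanometres per second along the fibril. In
quantum-dot-tracking experiments most binding events are *static* — the
enzyme sits within ~10 nm of its landing site for tens of seconds and then
dissociates — while a minority move processively, and a few percent make
sudden *jumps* (unbinding, brief diffusion through solution, rebinding
nearby). `cellodyn` packages the full analysis chain for such experiments:

- **`cellodyn.sim`** — a three-state kinetic simulator (solution / static /
  processive) that generates ground-truthed trajectories and, optionally,
  renders multi-page TIFF movies with fiducial beads, stage drift and
  Poisson photon noise;
- **`cellodyn.localize`** — sub-pixel 2D-Gaussian PSF fitting,
  nearest-neighbour track linking, and fiducial-based drift correction;
- **`cellodyn.segment`** — classification of each trajectory into static
  and processive segments and jump events using the operational
  definitions (static: <10 nm from the anchor; processive: >=10 nm over
  >=5 s; jump: >10 nm within two frames), plus the cohort inclusion
  filters;
- **`cellodyn.kinetics`** — windowed-exponential maximum-likelihood dwell
  fits with bootstrap confidence intervals, branching fractions, and the
  derived rate constants of the three-state model;
- **`cellodyn.pipeline` / the `cellodyn` CLI** — a reproducible
  simulate -> (render -> localize) -> segment -> fit -> report pipeline.

## The model

A bound enzyme occupies one of two states. Every exit is first order, so
dwell times are exponential and each state's observed time constant is the
inverse of its **total** exit rate; route constants follow from the
branching fractions (probability of an exit route = its rate over the
total):

    k_exit_processive = 1 / tau_processive        (tau from dwell MLE)
    k_off_processive  = f_unbind * k_exit_processive
    k_static          = (1 - f_unbind) * k_exit_processive

    k_exit_static     = 1 / tau_static            (pooled static tau)
    k_processive      = f_to_processive * k_exit_static
    k_off_static      = (1 - f_to_processive) * k_exit_static

Molecules land in the static state with probability `p_land_static`
(estimated from the first observed segment of each molecule). Dwell
samples are left-truncated by the analysis filters (events shorter than
the classification minimum are unusable) and right-windowed; the fitted
time constant is the MLE of an exponential restricted to that window,
which reduces to `mean - t_min` when there is no upper window.

## Worked example

Simulate a 2000-molecule experiment at the default study conditions
(1 frame/s, 1000 frames, 1.5 nm localization noise, landings in the first
500 s), segment it, fit the dwell distributions and derive the rates:

```
$ cat demo.yaml
sim:
  n_molecules: 2000
boot_iterations: 500
$ cellodyn report -c demo.yaml -o demo_run --seed 11
```

`demo_run/report.json` then contains (excerpt, this exact seed):

```
retained molecules: 1808
percent static: 91.2 / processive: 8.8
static tau:    85.4 s  (95% CI 81.1-89.2, n=1649)
velocity:      3.28 +/- 2.21 nm/s   (n=164 segments)
run length:    89.8 +/- 113.9 nm
proc duration: 26.0 +/- 18.9 s
```

and `demo_run/rates.json` holds the derived model:

```
k_exit_processive 0.0477 s^-1    k_off_processive 0.0100   k_static 0.0378
k_exit_static     0.0118 s^-1    k_off_static     0.0113   k_processive 0.00055
p_land_static     0.957
```

Reading these numbers: ~91% of retained molecules never moved measurably
and their binding durations fit a single exponential with an ~85 s time
constant; the processive minority moved at ~3.3 nm/s; exits from the
processive state split ~21/79 between unbinding and stalling back into the
static state, so the stall rate (`k_static`) dominates `k_exit_processive`.
The small `k_processive` is why the static state is rate-limiting: a bound
enzyme is far more likely to dissociate than to start a run.

Other entry points: `cellodyn simulate` (trajectories + ground truth
only), `cellodyn all` (including movie rendering and re-localization),
`cellodyn segment -i trajectories.csv` for externally produced tracking
tables (CSV schema: `molecule_id, frame, t_s, x_nm, y_nm, intensity`).

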