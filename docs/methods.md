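# Model and methods

`gridcan` implements a spiking continuous attractor network (CAN) model
of grid cells in layer II of the medial entorhinal cortex (MEC),
together with the measurement pipeline used to characterize grid-cell
physiology (rate maps, spatial autocorrelograms, grid score, field
geometry, population spectra, spike–phase coupling) and an experiment
layer for dorsoventral grid-scale presets, parameter-robustness sweeps
and cohort statistics.

## Populations and neuron model

Six neuron types are simulated, each on a 2-D neural sheet:

| type | role | count (full scale) |
|---|---|---|
| MEC LII stellate | grid cells | 1600 (40×40) |
| EC LI-II multipolar pyramidal | conjunctive (speed × direction) cells | 1600 |
| CA1 pyramidal | place cells | 1600 |
| EC LII axo-axonic / MEC LII basket / EC LII basket-multipolar | perisomatic interneurons | 834/833/833 (1200 each at the large grid scale) |

Every neuron follows the nine-parameter Izhikevich model

    C dv/dt = k (v − Vr)(v − Vt) − u + I
      du/dt = a (b (v − Vr) − u)

with spike cutoff at `Vpeak`, reset `v ← c`, `u ← u + d`.  Parameters
are type-specific (see `gridcan.params.NEURON_PARAMS`); the three
interneuron types share standard fast-spiking constants.  Integration
is forward Euler with `dt = 0.5` ms and two membrane-potential
substeps per step; `dt` is configurable and single-neuron tests verify
first-order convergence of spike counts under refinement.

A property worth knowing: the stellate parameter set (`b = 11.69` nS,
`a = 0.005`/ms) describes a *resonator*.  Its resting equilibrium loses
stability (Hopf-type) near 128 pA, well below the saddle-node current
of 177.8 pA given by the nullcline tangency, and a current step from
rest fires a transient spike from about 60 pA.  The closed-form
saddle-node value returned by `gridcan.neurons.rheobase` therefore
exceeds the step-protocol threshold for this cell class; for
integrator-like parameter sets (CA1 pyramidal, multipolar pyramidal)
the two agree within a few pA.  This was cross-checked against an
adaptive Runge–Kutta integration.

## Synapse model

Synapses use the Tsodyks–Markram short-term-plasticity scheme with
conductance-based receptor currents.  Per synapse, utilization `u`
(baseline 0, relaxing with `tau_u`) and resources `x` (baseline 1,
recovering with `tau_x`) evolve as: on each presynaptic spike the
utilization jumps first, `u ← u + U(1−u)`, then a fraction `R = u·x`
of resources is released, incrementing the fast and slow receptor
conductances by `g_fast·R` and `g_slow·R`.  Between spikes all
variables relax with *exact* exponential updates, so inter-spike
dynamics are independent of the integration step; the stepped path
reproduces the closed-form event-driven solution to 1e−9 for on-grid
spike times.

Receptors: AMPA/NMDA for excitatory classes, GABA_A/GABA_B for
inhibitory ones.  Reversal potentials are 0 mV (AMPA/NMDA), −70 mV
(GABA_A), −90 mV (GABA_B); slow decays are 150 ms.  The NMDA
conductance is gated by the magnesium-block factor
`s(v) = ((v+80)/60)² / (1 + ((v+80)/60)²)`; GABA_B is ungated.
Per-connection-class TM constants are the Hippocampome-derived values
in `gridcan.params.SYNAPSE_PARAMS`.  The printed conductances are
per-synapse peaks; population-scale multipliers (`SimConfig.weight_scale`)
adjust them for the simulated network size, and a separate
`slow_scale` controls the slow-receptor gain per class.  The default
GABA_B gain onto stellates is 0.05: at full strength the 150 ms
inhibition acts as global adaptation and quenches spatial pattern
formation rather than sculpting it.

## Connectivity

Sheets all span the same normalized 2-D coordinate space with periodic
boundaries; by default the metric is a *twisted torus* (wrapping in y
shifts x by half a sheet), which makes triangular bump lattices
commensurate with the sheet — a plain square torus frustrates hexagons
at 20–40 cell sheet sizes and is available via `topology="torus"`.

The center-surround (CS) connectivity is built per grid-scale preset:

* **stellate → interneuron**: each grid cell connects to interneurons
  on an annulus whose center is displaced from the cell by the preset
  `offset` *opposite* to the cell's preferred direction (N/S/E/W,
  tiled in 2×2 blocks).  The out-degree per interneuron type is drawn
  from a normal distribution (mean ± SD = 12 ± 2 at the intermediate
  scale; 5 and 16 at the large and small scales, following the
  dorsoventral connectivity trend).  Targets are picked *stratified by
  angle* around the ring: unstructured random subsets leave frozen
  heterogeneity that pins the attractor pattern.
* **interneuron → stellate**: each interneuron inhibits ~142 ± 66 grid
  cells within a wide annulus around itself, with Gaussian weight
  falloff concentrated at a small radius (`back_radius`, `back_sigma`).
  The membership band is deliberately much wider than the weight
  falloff so that the connection *census* reproduces the published
  count while the *dynamically effective* kernel stays tight.  The
  composition (ring ∘ local blob) gives each grid cell displaced ring
  inhibition: zero at the bump center, peaked near the ring radius —
  the requirement for multi-bump Turing patterning.  If the falloff is
  broad the composed kernel degrades into a disk and patterns die;
  this is the single most sensitive geometric choice in the model.
* **conjunctive → stellate** and **place → stellate** are 1-to-1,
  index-aligned, with unitary weights.

Stellate→IN connectivity never exceeds the 25.9% ceiling reported for
mouse MEC.  All sampling derives from one integer seed in fixed
(row-major presynaptic) order, so connection sets are reproducible.

## External drive

Conjunctive cell *i* receives
`I_i(t) = I_base + g_speed · s(t) · max(0, cos(θ(t) − θ_i))` where `s`
is running speed and `θ` the movement heading (movement direction, not
head direction); place cell *j* receives a Gaussian field drive
`g_place · exp(−‖p − c_j‖²/(2σ_p²))` with field centers tiling the
arena on the grid-sheet lattice.  A static, seeded ±15% per-cell
jitter is applied to the drive: identical tonically driven cells
otherwise lock into network-wide synchronous pulsing.  Stellates and
interneurons additionally receive independent per-step current noise
(default std 100 pA, from a counter-based deterministic generator), a
conventional stand-in for unmodeled synaptic bombardment.

Default drive constants (calibrated once, on the quarter-scale network):
`I_base = 500` pA (conjunctive cells tonically active near 25 Hz),
`g_speed = 25` pA·s/cm, `g_place = 400` pA, `σ_p = 3` cm; weight-scale
multipliers in `gridcan.engine.default_weight_scale`.

## Position tracking: what the model does and does not do

With stationary drive the grid-cell sheet settles into a persistent
multi-bump pattern whose surround radius (and hence lattice constant)
follows the preset ring radius — the dorsoventral scale machinery
works at the sheet level, and a suite test verifies the ordering.

Path integration by velocity-drive asymmetry — the textbook CAN
translation mechanism — does **not** operate at the simulated network
sizes.  The bump lattice is pinned to the neural sheet: bumps span
only ~2–3 cells, each of the four direction subpopulations contributes
about one cell per bump, and measured bump translation under constant
virtual velocity is exactly zero for drive asymmetries up to 3× the
baseline and offsets up to half the ring radius.  Fluid translation in
this model class is known to require sheets on the order of 100×100
cells.  Position tracking therefore rests on the place-cell pathway:
the moving place-drive anchor pins the pattern phase to the animal's
position (drift correction taken to the small-network limit).  The
consequence, measured honestly by the acceptance-style tests, is that
population activity is reliably elevated at the sheet position
corresponding to the animal (anchored tracking), individual cells can
reach grid scores of 0.5–0.97, but the *median* designated-cell grid
score at the quarter-scale study conditions fluctuates around the 0.2
acceptability threshold (−0.07 to +0.18 across seeds), and map-level
spacing does not resolve the scale presets.  These two checks are
retained in the test suite in their full original form and currently
fail; the sheet-level equivalents pass.

## Synthetic foraging trajectories

`synth_trajectory` emulates open-field foraging in a 45×45 cm arena: a
smooth heading random walk (angular diffusion 2.2 rad/√s) with an
Ornstein–Uhlenbeck speed process (mean 12 cm/s, sd 7 cm/s, 1 s
relaxation, clipped at 90 cm/s so fast running stays below 2% of
samples), reflective walls, 50 Hz sampling.  A 600 s track covers ≥80%
of 3 cm occupancy bins.  It does not model thigmotaxis, grooming
pauses, or reward-directed runs — trajectory statistics are homogeneous
in time, so tests passing on synthetic tracks say nothing about
behaviorally inhomogeneous sampling.

## Analysis pipeline

Rate maps: spikes and occupancy binned at 3 cm (2 cm for the
quarter-scale model, whose fields are proportionally smaller),
separately Gaussian-smoothed (σ equal to the bin), divided; bins with
under 0.1 s raw occupancy are unvisited and excluded (never
zero-filled).  Autocorrelogram: Pearson correlation at every 2-D lag
over ≥20 overlapping valid bins; zero-variance or under-overlap lags
are 0 by convention.  Grid score: annulus rotational correlation,
`min(r60, r120) − max(r30, r90, r150)`, with the annulus resampled to
polar coordinates so every comparison angle carries identical
interpolation error, inner radius just outside the central peak, outer
radius swept with the maximum score reported.  Fields: connected
components above 0.2 of the map peak with ≥9 bins (≥5 at 2 cm);
size is the equal-area-circle diameter, so a Gaussian field of width σ
measures 2σ√(2 ln 5).  Spacing: median distance of the six inner
autocorrelogram peaks (falling back to nearest-neighbour field
distances); orientation: smallest inner-peak angle mod 60°.
A square analysis window superimposes a 4-fold boundary artifact of
about −0.13 on the grid score of radially symmetric maps; the
ring-map fixture therefore uses the inscribed circular window.

Spectra: population rates (1 ms bins, spikes/s per neuron) are
Gaussian-smoothed with a 3 ms window, mean-subtracted and passed to a
multitaper PSD (time-bandwidth 4, 7 tapers); band fractions integrate
delta 1–4, theta 4–12, beta 12–25 and gamma 25–100 Hz over the 1–100 Hz
total.  The 3 ms smoothing necessarily attenuates gamma relative to
beta (about 2:1 in power at 50 vs 20 Hz); it can be disabled per call.
Spike–phase coupling: the reference rate is band-passed ±3 Hz around
the band's spectral peak, phases come from the analytic signal, and
coupling is the mean resultant vector length (MRVL) with the standard
Rayleigh approximation `p ≈ exp(√(1+4n+4(n²−R²n²)) − (1+2n))`
(cross-checked against `pingouin`).

Cohort comparisons use the two-sided Wilcoxon rank-sum (exact
enumeration for n ≤ 25 per group), reporting medians and IQRs; type-I
error is calibrated to 5 ± 2% at n = 29 in the suite.

## Experiments

`run_scale_preset` runs simulate→analyze for one dorsoventral preset
on a given trajectory, reporting metrics for the nine designated cells
(the central 3×3 block of the grid sheet — chosen as the summary set
before any acceptance evaluation; configurable).  It rescales the
stellate→IN weight multiplier by 12/out-degree so total surround
inhibition is comparable across presets.  `run_sweep` evaluates one or
two IM/TM parameters on (by default) 9-value grids containing the
default value, rebuilding the network and re-running a shortened
simulation per point; TM sweeps move all three stellate→IN classes
together.  Failures at a grid point mark that point NaN rather than
aborting.  Biological parameter ranges are configuration inputs (the
evolutionary-algorithm machinery that produced them is out of scope);
heatmaps interpolate bilinearly for display only.

## Problem sizes and defaults used by the automated checks

The test suite and acceptance protocol use the quarter-scale network
(20×20 grid sheet, ~1830 neurons, ~58k synapses), 300–600 s synthetic
trajectories, and the full 9300-neuron network for connectivity-only
checks.  A 600 s quarter-scale simulation takes on the order of 1.5
minutes on one CPU core with the numba engine.

## Known limitations

* No velocity-driven path integration at feasible network sizes (see
  above); position tracking is place-anchored.
* No long-term plasticity, no stochastic vesicle release, no
  conduction-delay heterogeneity (1 ms uniform delay).
* No theta-rhythmic or inhibitory speed coding, boundary cells, or
  visual landmarks.
* No grid-cell → place-cell feedback; place fields are imposed, not
  learned.
* Single-compartment neurons; interneuron IM constants are generic
  fast-spiking values rather than type-specific fits.
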