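# gridcan

A spiking continuous attractor network (CAN) model of medial entorhinal
cortex (MEC) grid cells, with the full grid-cell physiology analysis
suite: spatial rate maps, autocorrelograms and grid scores, field size
and spacing, population spectra and spike–phase coupling, dorsoventral
grid-scale presets, and parameter-robustness sweeps.

It is aimed at computational neuroscientists who want a desk-scale,
pure-Python/numba reimplementation of a data-constrained grid-cell
circuit — Izhikevich neurons with type-specific constants,
Tsodyks–Markram synapses with receptor kinetics, and center-surround
ring connectivity between stellate cells and three perisomatic
interneuron types — plus the standard measurement stack used on real
recordings.

## The model in brief

Grid cells live on a 2-D neural sheet with periodic (twisted-torus)
boundaries.  Each cell `i` follows the nine-parameter Izhikevich model

    C dv/dt = k (v − Vr)(v − Vt) − u + I,   du/dt = a (b (v − Vr) − u),

spiking at `Vpeak` with reset `(c, u + d)`.  Synaptic release obeys the
Tsodyks–Markram scheme — on a presynaptic spike `u ← u + U(1 − u)`,
`R = u·x`, `x ← x − R` — feeding AMPA/NMDA or GABA_A/GABA_B
conductances with class-specific kinetics.  Each stellate cell excites
interneurons on a ring displaced opposite to its preferred direction
(N/S/E/W); interneurons inhibit stellate cells around themselves.  The
composed center-surround interaction stabilizes a hexagonal multi-bump
activity pattern whose lattice constant follows the ring radius
(small / intermediate / large dorsoventral presets with 16 / 12 / 5
stellate→interneuron connections per cell).  Conjunctive cells supply
speed- and direction-tuned excitation; CA1 place cells anchor the
pattern phase to the animal's position (drift correction).  The grid
score of a rate map's autocorrelogram is
`min(r60, r120) − max(r30, r90, r150)` over an annulus, with 0.2 the
acceptability threshold.

See `docs/methods.md` for the complete model description, calibration
choices, and an honest account of what the desk-scale model does and
does not reproduce.

## Worked example

Simulate one minute of synthetic foraging on the quarter-scale network
and analyze two grid cells (grid cells occupy neuron ids `0..399` on
the 20×20 sheet):

```bash
gridcan simulate --duration 30 --seed 1 --grid-side 20 --out demo
gridcan analyze --spikes demo/spikes.tsv --trajectory demo/trajectory.tsv \
                --cell 210 --cell 230 --out demo/analysis
```

prints

```
wrote demo/spikes.tsv (1002724 spikes)
analyzed 2 cells -> demo/analysis/grid_metrics.tsv
```

and `demo/analysis/grid_metrics.tsv` holds per-cell metrics, e.g.

```
cell  grid_score  mean_rate  peak_rate  field_size_cm  spacing_cm
210   -0.10       0.63       3.87       13.5           18.0
230   -0.04       2.77       9.21       18.8
```

— cell 210 fires at 0.63 spikes/s with ~13.5 cm fields about 18 cm
apart; 30 s of coverage is far too short for a meaningful grid score
(use ≥300 s).  `demo/census.tsv` summarizes the connectivity, e.g. a
mean stellate→axo-axonic out-degree of 11.9 ± 1.9 at quarter scale.

From Python:

```python
from gridcan.drive import synth_trajectory
from gridcan.experiments import run_scale_preset

traj = synth_trajectory(300.0, seed=11)          # 5 min forage, 45x45 cm
df = run_scale_preset("intermediate", traj=traj, seed=1, grid_side=20)
print(df[["cell", "grid_score", "mean_rate", "spacing_cm"]])
```

Parameter-robustness sweeps (grid score versus Izhikevich or
Tsodyks–Markram constants, nine values per parameter) run via
`gridcan sweep --params b,d --out sweep_bd/`.

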