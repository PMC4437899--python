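# hybrot

Closed-loop simulation and analysis of a **cultured neural network steering a
robot**. A dissociated hippocampal culture grown on a 60-electrode MEA (an
8×8 grid minus corners; 59 recording electrodes plus a ground at row 5,
column 1) acts as the controller of a two-wheel differential-drive robot
searching for an object at the center of a square arena. The package
implements both culture layouts used in such experiments — an unstructured
**random** culture and a **'4Q'** culture physically divided into four
quadrant wells interconnected by microchannels — and asks the quantitative
question: *does the hierarchical '4Q' topology route stimuli more
specifically, and does the robot it controls perform better and improve
within a session?*

## What it contains

* **Synthetic culture** (`hybrot.culture`) — a 1 ms-step leaky
  integrate-and-fire network (400 neurons, 80 % excitatory,
  distance-dependent connectivity, Tsodyks–Markram-style short-term
  depression, distance-dependent conduction delays, Poisson background
  drive). It produces spontaneous network-wide bursts, stimulus-evoked
  responses whose spatial specificity depends on topology, and a slow
  bounded *pathway gain* that strengthens a stimulated input's local
  synapses after successfully decoded stimulations.
* **Recording-side signal processing** (`hybrot.signal`) — threshold spike
  detection (−5× robust noise SD, 1 ms lockout), stimulation-artifact
  blanking (4 ms per pulse), evoked-response windowing with pre-stimulus
  baseline correction, responder sets, and population-burst detection.
* **The closed-loop protocol** (`hybrot.protocol`) — candidate probing on a
  30 s cadence, input selection by responder-set dissimilarity (1 − Jaccard),
  output-area / other-area assignment, sensory encoding (object left →
  pair-pulse on input 1; right → input 2), winner-take-all decoding between
  the two output areas, and 15-minute trials at a ≥ 20 s stimulation cadence
  repeated over three phases with rests.
* **Robot and arena** (`hybrot.robot`) — exact unicycle kinematics, bearing
  sensing, reach detection (closed 0.1 m ball), corner starts.
* **Statistics** (`hybrot.stats`) — redundancy ratio
  |A ∩ B| / |A ∪ B| between the responder sets of two stimuli, output- vs
  other-area evoked rates, evoked-electrode fractions, correct-turning
  percentages per direction, times-to-reach, phase evolution, and the
  two-sample Kolmogorov–Smirnov test (significance at P < 0.05).

The stimulus used throughout is the standard sensory code: a **pair-pulse**,
±230 mV, negative phase first, 1.5 ms phase duration, two pulses 50 ms
apart.

## Worked example

```python
from hybrot import CultureParams, build_culture, run_experiment, performance

culture = build_culture(CultureParams(topology="4Q", seed=1))
log = run_experiment(culture, seed=1)   # probe -> select inputs -> 3 x 15 min
perf = performance(log)
print(perf.phases[["n_decisions", "correct_left_pct", "correct_right_pct",
                   "n_reaches", "mean_time_to_reach_s"]].round(1))
```

prints

```
       n_decisions  correct_left_pct  correct_right_pct  n_reaches  mean_time_to_reach_s
phase
1               15             100.0              100.0         14                  61.1
2               15             100.0              100.0         14                  61.1
3               20              90.0               90.0         13                  66.3
```

Each row is one 15-minute phase: how many turn decisions the culture made,
the percentage decoded correctly per required direction (chance for a binary
decoder is 50 % per direction, 25 % jointly), how often the robot reached
the object, and the mean time per reach. After the run,
`culture.pathway_gains` shows the plasticity state
(`{'r2c2': 2.0, 'r2c7': 2.0}` — both input pathways strengthened to the
cap).

The same pipeline is available from the shell:

```bash
hybrot simulate --topology 4Q --duration 120 --seed 0 --out out/sim
hybrot experiment --topology 4Q --seed 1 --out out/exp   # log + figures
hybrot analyze out/exp/experiment.jsonl                  # stats from logs only
```

## Layout

```
src/hybrot/
  core.py      geometry, rasters, stimulus commands, TSV I/O
  culture.py   the synthetic spiking culture (random / 4Q)
  signal.py    spike detection, artifact blanking, evoked responses, bursts
  robot.py     differential-drive kinematics, arena, bearing
  protocol.py  probing, area assignment, encode/decode, trials, experiments
  stats.py     redundancy, performance, K-S, phase evolution
  cli.py       the `hybrot` command-line interface
docs/methods.md   model description, parameter choices, limitations
```
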