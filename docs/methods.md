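# Methods

This note documents the models and analysis conventions implemented in
`hybrot`, the parameter choices that matter, and what the synthetic data can
and cannot establish.

## The synthetic culture

The culture is a discrete-time (dt = 1 ms) network of leaky
integrate-and-fire neurons intended to reproduce, at electrode level, the
qualitative phenomenology of a dissociated hippocampal culture on an MEA at
2–3 weeks in vitro: long quiescent stretches punctuated by network bursts,
stimulus-evoked responses that engage a region rather than the whole dish,
and topology-dependent routing of those responses. It is **not** a
biophysical model; membrane units are threshold-relative, not millivolts.

**Membrane and synapses.** Threshold 20, reset 0, membrane time constant
20 ms, absolute refractory period 5 ms. A presynaptic spike delivers
`w · x` to each target after a distance-dependent conduction delay
(`distance / axon_velocity`, 50 µm/ms, clipped to 1–20 ms). Heterogeneous
delays are essential: with a uniform 1 ms delay a strong stimulus collapses
the whole response into a 2-step synchronous population spike that dies
instantly and largely disappears into the artifact-blanking window.
Excitatory synapses depress (Tsodyks–Markram-style resources `x`, release
fraction U = 0.2 per spike, recovery τ_rec = 2 s); depression terminates
bursts and spaces them out. Inhibitory synapses (20 % of neurons) are
strong (w = −30 vs. +10.5 excitatory) and static; strong inhibition makes
evoked responses approximately all-or-none, which is what gives the evoked
fraction statistics their observed culture-to-culture spread.

**Background drive.** Each neuron receives Poisson impulses
(rate 1.4 Hz, amplitude 12, i.e. ≈ 0.6 × threshold). Spontaneous firing and
burst ignition are emergent: coincident impulses plus recurrent
amplification ignite a burst when resources have recovered. At
`noise_rate = 0` the network is exactly silent.

**Geometry.** Neurons (400 by default) are placed uniformly over a dish
extending 200 µm beyond the 200 µm-pitch electrode grid. In the '4Q'
topology positions are confined to four quadrant wells separated by
100 µm-wide cell-free margins at the midlines; connectivity (p = 0.35
within 400 µm) is restricted to within-well pairs plus 20 bidirectional
excitatory bridge connections per adjacent quadrant pair at 0.7× nominal
weight, standing in for the microchannels. With `bridge_count = 0` the
adjacency is exactly block-diagonal and a stimulus in one quadrant can
evoke nothing outside it (an exact invariant used in tests). The population
count deliberately exceeds what the nominal plating density (50–80
cells/mm², recorded as metadata) implies, because recurrent burst dynamics
need a minimum population.

**Recording and stimulation.** Each neuron is recorded by its nearest
electrode if within 75 µm (calibrated; nominally half the pitch, reduced so
that output-area evoked-electrode fractions land at the observed ≈ 60 %
level). A pulse at an electrode injects a Gaussian-falloff drive (peak 60,
σ = 133 µm, truncated at one pitch) into nearby neurons; in '4Q' cultures
the walls confine the spread to the electrode's quadrant.

**Slow plasticity.** Each designated input electrode carries a pathway gain
that starts at 1, multiplies both its direct stimulation drive and the
outgoing synaptic efficacy of the neurons under the electrode (bridge
synapses excluded — strengthening is local to the well), is multiplied by
1.05 after every successfully decoded stimulation, and saturates at 2. This
is a deliberately minimal, bounded stand-in for the use-dependent,
minutes-scale strengthening that underlies within-session improvement; no
mechanistic claim is attached to it. Failures never decrease the gain.
Excluding bridges from the boost matters: otherwise a strengthened pathway
ignites the *adjacent* quadrant late in the response window and decoding
degrades as the gain grows.

## Signal processing

Spike detection uses the community-standard negative threshold at
5 × robust noise SD (median absolute deviation / 0.6745) with a 1 ms
lockout; it is scale-invariant by construction. Stimulation artifacts are
modeled (in synthesized voltage traces) as 4 ms saturating transients on
every electrode at every pulse and are handled by blanking 4 ms per pulse —
both pulses of the 50 ms pair are blanked independently, and all
evoked-response counting starts after the blanking window.

**Evoked responses and baseline correction.** An evoked response is the
per-electrode spike count in a window after the first pulse (0.5 s by
default for decoding and responder statistics; the classic 2 s display
window is available). The protocol works with *baseline-corrected*
responses: the count in the immediately preceding window of the same length
is subtracted (clipped at zero). Without this correction, regions that
burst spontaneously at a high rate masquerade as reliable responders and
win output-area selection, which confounds "evoked" with "active". An
electrode *responds* if its corrected count is ≥ 1 (the criterion and the
window are configuration, reported in output metadata, since "responding"
is not defined quantitatively anywhere authoritative).

**Bursts** are runs of time bins (0.1–1 s) in which more than a threshold
fraction (default 50 %) of the session's active electrodes fire; consecutive
hot bins merge into maximal intervals. Under default parameters '4Q'
cultures produce several network-wide bursts per 2 minutes (synchronized
across quadrants through the bridges); simulated bursts last a few hundred
milliseconds up to ~1 s, somewhat shorter than the seconds-long bursts of
mature cultures — a known limitation.

## Protocol conventions

* Probing: each candidate (default: one interior electrode per quadrant)
  receives 3 pair-pulse probes 30 s apart; per-candidate maps are averaged.
  Probing stops early once two candidates evoke network firing (≥ 4
  responding electrodes).
* Input selection maximizes summed pairwise dissimilarity (1 − Jaccard on
  responder sets); ties break toward the most physically separated
  electrode pair, then lexicographically — deterministic by construction.
* Output areas: candidate areas are the four quadrants for both topologies
  (the array's natural regions, and the granularity at which the
  output/other comparison is made); a contiguous-responder-cluster scheme
  is available as an option for unstructured cultures. Assignment is greedy
  by mean evoked count per electrode, strongest claim first; two inputs
  never share an output area (a collision pushes the weaker input to its
  next-best remaining region and is logged). The input's other area is the
  rest of its responder set.
* Encoding: bearing > +10° (object to the robot's left) → pair-pulse on
  input 1; < −10° → input 2; inside the deadband no stimulation is sent.
* Decoding: winner-take-all on mean baseline-corrected evoked count per
  electrode between the two output areas; exact ties draw uniformly from
  the session generator and are flagged in the log.
* Trials: 15 minutes exactly, decisions every 20 s (the minimum
  inter-stimulation interval), three phases separated by 3-minute rests
  (within the stated 2–4 min range), pathway gains carried across phases.
  The neural side is simulated event-drivenly: each stimulation runs the
  network for ~1.6 s around the pulse pair (baseline window + response
  window); between stimulations the synaptic state relaxes to its
  inter-burst baseline (`init_resources` = 0.7), which is accurate because
  τ_rec ≪ 20 s. This is what makes a 45-minute session simulable in
  seconds without changing any decision-relevant quantity.

## Robot

Exact arc-integrated unicycle kinematics; wall-clamped 2 × 2 m arena;
object at the center; reach = closed 0.1 m ball. The camera is idealized as
exact bearing sensing. Speed is 0.02 m/s between decisions: with the 20 s
decision cadence fixed by the stimulation protocol, legs must be well under
the arena half-width or the robot provably orbits the object (with 1 m legs
and any fixed turn quantum there is a stable polygonal limit cycle that
never enters the reach ball). For the same reason the executed turn is
`min(|bearing|, 60°)` in the decoded direction — the camera supplies the
magnitude, the culture only the direction. Start poses sit at the four
corners facing along a wall, alternating left-turn-first and
right-turn-first corners, and each reach resettles the robot at the next
corner so both directions are exercised within a session.

## Statistics

* Redundancy ratio of two stimuli = |A ∩ B| / |A ∪ B| over responder sets
  (the union denominator makes it a pure overlap measure in [0, 1]; the
  full-array denominator is available via a flag). Undefined (flagged, not
  zero) when both sets are empty.
* Correct-turning percentage is computed per required direction, only over
  decisions whose required turn is that direction; a direction with no
  decisions is undefined, never 0. Joint correctness is the product of the
  two per-direction fractions (chance 25 % for a uniform binary decoder).
* Times-to-reach restart their clock at every resettling, so one trial
  contributes several intervals.
* Significance uses the two-sided two-sample K-S test (exact small-sample
  null for n ≤ 25, asymptotic otherwise), threshold P < 0.05, no
  multiple-testing correction.

## What the synthetic data show — and what they do not

Under default parameters the pipeline reproduces the target phenomenology:
'4Q' redundancy ratios lie near 0 while random-culture ratios are large
(K-S P < 0.05 at 10 vs 10); output-area evoked fractions average ≈ 60 % in
'4Q' and ≈ 65 % in random cultures (both within the reported
between-culture spreads of ±20 points, though the random-culture mean runs
a few points above the reported 58 % — a minority of synthetic random
cultures develop one dominant, near-always-igniting pathway, a heavy-tail
consequence of uniform position sampling; homogenizing positions removes
those cultures but makes *every* culture reliable and overshoots far
worse); final-phase correct turning exceeds 80 % per direction; and median
reach times are near one minute, well under the several-minute scale of the
physical system (the idealized camera and instantaneous decisions make the
simulated robot faster; the bound, not the value, is the meaningful
comparison). Passing these checks shows the pipeline's logic and statistics
behave correctly on data with the right structure; it does not validate the
neuron model against real recordings, and the within-session improvement
rests on a phenomenological gain rule, not on measured synaptic physiology.

Numerical conventions worth knowing: spike times are quantized to the 1 ms
step and serialized at microsecond precision (lossless round-trips);
geometry ties (equal-mean areas, equal dissimilarities) break
deterministically toward lower indices/labels; every stochastic choice in a
session draws from one seeded generator recorded in the log header, and
fixed (culture, schedule, seed) gives bit-identical rasters.
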