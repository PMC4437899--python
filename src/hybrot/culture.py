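"""Synthetic dissociated-culture model on the MEA.

A discrete-time (1 ms) leaky integrate-and-fire network with
Tsodyks–Markram-style short-term synaptic depression stands in for the
biological culture.  Two topologies are supported:

* ``'random'`` — distance-dependent recurrent connectivity across the whole
  dish, giving dish-wide spontaneous bursts and strongly overlapping evoked
  responses regardless of where stimulation is applied.
* ``'4Q'`` — the same local rule applied inside four quadrant wells separated
  by walls, with a small number of bridge connections per adjacent quadrant
  pair standing in for the microchannels.  Evoked activity then stays mostly
  compartmentalized while spontaneous bursts can still spread network-wide.

On top of the fast synaptic dynamics, each designated input electrode carries
a slow, bounded *pathway gain* that multiplies its stimulation drive and is
ratcheted up on successfully decoded stimulations.  This is a deliberately
minimal stand-in for the use-dependent, minutes-scale strengthening that the
closed-loop experiments rely on; it is not a biophysical plasticity model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ConfigurationError,
    MEAGeometry,
    Raster,
    StimulusCommand,
    electrode_label,
    make_geometry,
    parse_electrode,
)

__all__ = [
    "STPParams",
    "CultureParams",
    "Culture",
    "build_culture",
    "simulate",
    "update_pathway_gain",
    "voltage_traces",
]

DT_MS = 1.0  # simulation step, ms

# Membrane / synapse constants (model units; threshold-relative, not mV).
V_THRESH = 20.0
TAU_M_MS = 20.0
REFRACTORY_MS = 5.0
ARTIFACT_MS = 4.0  # saturating transient painted into voltage traces per pulse


@dataclass(frozen=True)
class STPParams:
    """Short-term depression parameters (release fraction + recovery)."""

    utilization: float = 0.2  # fraction of resources consumed per spike
    tau_rec: float = 2.0  # s, resource recovery time constant
    tau_facil: float = 0.0  # s, 0 disables facilitation

    def __post_init__(self):
        if not 0 < self.utilization <= 1:
            raise ConfigurationError("utilization must be in (0, 1]")
        if self.tau_rec <= 0:
            raise ConfigurationError("tau_rec must be positive")


@dataclass(frozen=True)
class CultureParams:
    """Parameters of the synthetic culture.

    ``plating_density`` is informational metadata (cells/mm² of the source
    preparation); the simulated population size is set by ``n_neurons``, which
    deliberately exceeds the density-implied count because recurrent burst
    dynamics need a minimum population.
    """

    topology: str = "4Q"
    n_neurons: int = 400
    excitatory_fraction: float = 0.8
    plating_density: float = 65.0  # cells/mm², informational
    connection_radius: float = 400.0  # µm
    within_prob: float = 0.35
    bridge_count: int = 20  # inter-quadrant connections per adjacent pair
    bridge_weight_scale: float = 0.7
    w_exc: float = 10.5  # synaptic efficacy at full resources
    w_inh: float = 30.0  # magnitude; applied negative
    stp: STPParams = field(default_factory=STPParams)
    pathway_gain_rate: float = 0.05  # multiplicative increment per success
    pathway_gain_cap: float = 2.0
    noise_rate: float = 1.4  # Hz, rate of background drive impulses per neuron
    noise_amp: float = 12.0  # amplitude of one background impulse (threshold = 20)
    init_resources: float = 0.7  # synaptic resources at session start (inter-burst state)
    stim_strength: float = 60.0  # peak direct drive at the stimulated electrode
    axon_velocity: float = 50.0  # µm/ms conduction speed -> distance-dependent delays
    max_delay_ms: float = 20.0
    stim_radius: float = 200.0  # µm, 1 electrode pitch
    detect_radius: float = 75.0  # µm, effective spike pickup radius
    wall_margin: float = 100.0  # µm kept cell-free on each side of a 4Q wall
    dish_margin: float = 200.0  # µm of dish beyond the electrode grid
    seed: int = 0

    def __post_init__(self):
        if self.topology not in ("random", "4Q"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if not 0 < self.excitatory_fraction < 1:
            raise ConfigurationError("excitatory_fraction must be in (0, 1)")
        if self.bridge_count < 0:
            raise ConfigurationError("bridge_count must be >= 0")
        if self.noise_rate < 0 or self.pathway_gain_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.topology == "4Q" and self.n_neurons < 4:
            raise ConfigurationError("'4Q' topology needs at least 4 neurons")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CultureParams":
        d = dict(d)
        if "stp" in d and isinstance(d["stp"], dict):
            d["stp"] = STPParams(**d["stp"])
        return cls(**d)


# adjacent quadrant pairs (diagonals are not connected by microchannels)
ADJACENT_QUADRANTS = [(1, 2), (1, 3), (2, 4), (3, 4)]


@dataclass
class Culture:
    """A built synthetic culture: positions, connectivity, coupling, gains."""

    params: CultureParams
    geometry: MEAGeometry
    positions: np.ndarray  # (N, 2) µm
    excitatory: np.ndarray  # (N,) bool
    weights: np.ndarray  # (N, N); weights[i, j] = synapse j -> i
    delays: np.ndarray  # (N, N) int steps; conduction delay of synapse j -> i
    bridge: np.ndarray  # (N, N) bool; True for inter-quadrant bridge synapses
    neuron_quadrant: np.ndarray  # (N,) int, 1..4 by dish position
    electrode_of: np.ndarray  # (N,) index into recording electrode list, or -1
    pathway_gains: dict[str, float] = field(default_factory=dict)
    _stim_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def recording_electrodes(self) -> list[str]:
        return self.geometry.recording_electrodes

    def designate_inputs(self, electrodes: Iterable[str]) -> None:
        """Mark electrodes as protocol inputs; their pathway gains start at 1."""
        for e in electrodes:
            label = electrode_label(*parse_electrode(e))
            if not self.geometry.is_recording(label):
                raise ConfigurationError(f"{label} is not a recording electrode")
            self.pathway_gains.setdefault(label, 1.0)

    def gain(self, electrode: str) -> float:
        return self.pathway_gains.get(electrode_label(*parse_electrode(electrode)), 1.0)

    def stim_drive(self, electrode: str) -> np.ndarray:
        """Direct drive vector (per neuron) for a pulse at ``electrode``, gain 1.

        Gaussian falloff with distance, truncated at ``stim_radius``; in '4Q'
        cultures the walls confine current spread to the electrode's quadrant.
        """
        label = electrode_label(*parse_electrode(electrode))
        if label not in self._stim_cache:
            p = self.params
            ex, ey = self.geometry.position(label)
            d = np.hypot(self.positions[:, 0] - ex, self.positions[:, 1] - ey)
            sigma = p.stim_radius / 1.5
            drive = p.stim_strength * np.exp(-((d / sigma) ** 2))
            drive[d > p.stim_radius] = 0.0
            if p.topology == "4Q":
                q = self.geometry.quadrant_of(label)
                drive[self.neuron_quadrant != q] = 0.0
            self._stim_cache[label] = drive
        return self._stim_cache[label]


def _dish_bounds(geometry: MEAGeometry, margin: float) -> tuple[float, float]:
    lo = -margin
    hi = (geometry.cols - 1) * geometry.electrode_pitch + margin
    return lo, hi


def build_culture(params: CultureParams, geometry: MEAGeometry | None = None) -> Culture:
    """Build a culture deterministically from its parameter set (incl. seed)."""
    geometry = geometry or make_geometry()
    rng = np.random.default_rng(params.seed)
    n = params.n_neurons
    lo, hi = _dish_bounds(geometry, params.dish_margin)
    mid = ((geometry.cols - 1) / 2) * geometry.electrode_pitch  # wall midline, both axes

    if params.topology == "4Q":
        # sample inside the four wells: walls (width 2*wall_margin) on the midlines
        quad = rng.integers(1, 5, size=n)
        xs = np.empty(n)
        ys = np.empty(n)
        for i, q in enumerate(quad):
            right = q in (2, 4)
            lower = q in (3, 4)  # rows 5-8 have larger y
            x_lo = mid + params.wall_margin if right else lo
            x_hi = hi if right else mid - params.wall_margin
            y_lo = mid + params.wall_margin if lower else lo
            y_hi = hi if lower else mid - params.wall_margin
            xs[i] = rng.uniform(x_lo, x_hi)
            ys[i] = rng.uniform(y_lo, y_hi)
        positions = np.column_stack([xs, ys])
    else:
        positions = rng.uniform(lo, hi, size=(n, 2))
        quad = (
            1
            + (positions[:, 0] > mid).astype(int)
            + 2 * (positions[:, 1] > mid).astype(int)
        )

    excitatory = rng.random(n) < params.excitatory_fraction

    # distance-dependent recurrent connectivity
    dx = positions[:, 0][None, :] - positions[:, 0][:, None]
    dy = positions[:, 1][None, :] - positions[:, 1][:, None]
    dist = np.hypot(dx, dy)
    candidate = (dist <= params.connection_radius) & ~np.eye(n, dtype=bool)
    if np.isinf(params.connection_radius):
        candidate = ~np.eye(n, dtype=bool)
    if params.topology == "4Q":
        same_quad = quad[:, None] == quad[None, :]
        candidate &= same_quad
    conn = candidate & (rng.random((n, n)) < params.within_prob)

    weights = np.zeros((n, n))
    weights[:, excitatory] = params.w_exc
    weights[:, ~excitatory] = -params.w_inh
    weights[~conn] = 0.0

    # distance-dependent conduction delays (>= 1 step)
    max_steps = max(1, int(round(params.max_delay_ms / DT_MS)))
    delay_steps = np.clip(
        np.round(dist / (params.axon_velocity * DT_MS)), 1, max_steps
    ).astype(np.int16)
    delays = np.where(weights != 0, delay_steps, 0).astype(np.int16)

    bridge = np.zeros((n, n), dtype=bool)
    if params.topology == "4Q" and params.bridge_count > 0:
        for qa, qb in ADJACENT_QUADRANTS:
            ia = np.flatnonzero(quad == qa)
            ib = np.flatnonzero(quad == qb)
            if len(ia) == 0 or len(ib) == 0:
                continue
            for _ in range(params.bridge_count):
                a = ia[rng.integers(len(ia))]
                b = ib[rng.integers(len(ib))]
                w = params.w_exc * params.bridge_weight_scale
                # bidirectional microchannel; bridges are excitatory
                weights[b, a] = w
                weights[a, b] = w
                delays[b, a] = delay_steps[b, a]
                delays[a, b] = delay_steps[a, b]
                bridge[b, a] = True
                bridge[a, b] = True

    # couple each neuron to its nearest recording electrode within detect_radius
    rec = geometry.recording_electrodes
    epos = np.array([geometry.position(e) for e in rec])
    d2e = np.hypot(
        positions[:, 0][:, None] - epos[None, :, 0],
        positions[:, 1][:, None] - epos[None, :, 1],
    )
    nearest = np.argmin(d2e, axis=1)
    electrode_of = np.where(
        d2e[np.arange(n), nearest] <= params.detect_radius, nearest, -1
    )

    return Culture(
        params=params,
        geometry=geometry,
        positions=positions,
        excitatory=excitatory,
        weights=weights,
        delays=delays,
        bridge=bridge,
        neuron_quadrant=np.asarray(quad, dtype=int),
        electrode_of=electrode_of,
    )


def _expand_schedule(
    schedule: Sequence[tuple[float, StimulusCommand]], duration: float
) -> list[tuple[float, StimulusCommand]]:
    prev = -np.inf
    for t, cmd in schedule:
        if not isinstance(cmd, StimulusCommand):
            raise ConfigurationError("schedule entries must carry a StimulusCommand")
        if t <= prev:
            raise ConfigurationError("schedule times must be strictly increasing")
        if t < 0 or cmd.pulse_times(t)[-1] >= duration:
            raise ConfigurationError("stimulus (all pulses) must fit within the session")
        prev = t
    return list(schedule)


def simulate(
    culture: Culture,
    duration: float,
    schedule: Sequence[tuple[float, StimulusCommand]] = (),
    seed: int = 0,
) -> Raster:
    """Run the network for ``duration`` seconds and return the recorded raster.

    The schedule is a time-sorted list of (onset_s, StimulusCommand); each
    pulse of each command injects direct drive around its electrode, scaled by
    that pathway's current gain.  The gain also multiplies the *outgoing*
    synaptic efficacy of the neurons under the stimulated electrode, so a
    strengthened pathway both recruits more neurons directly and propagates
    its volley more effectively.  Fixed (culture, schedule, seed) gives a
    bit-identical raster.
    """
    p = culture.params
    schedule = _expand_schedule(schedule, max(duration, 1e-9))
    rng = np.random.default_rng(seed)
    n = culture.n_neurons
    n_steps = int(round(duration * 1000.0 / DT_MS))
    decay = float(np.exp(-DT_MS / TAU_M_MS))
    refr_steps = int(round(REFRACTORY_MS / DT_MS))
    u = p.stp.utilization
    rec_step = DT_MS / 1000.0 / p.stp.tau_rec
    p_bg = p.noise_rate * DT_MS / 1000.0

    # pulse step -> accumulated drive vector
    pulse_drive: dict[int, np.ndarray] = {}
    pulse_sec: list[float] = []
    for t0, cmd in schedule:
        base = culture.stim_drive(cmd.electrode) * culture.gain(cmd.electrode)
        # amplitude enters relative to the standard ±230 mV stimulus
        base = base * (cmd.amplitude / 230.0)
        for tp in cmd.pulse_times(t0):
            step_idx = int(round(tp * 1000.0 / DT_MS))
            if step_idx < n_steps:
                pulse_drive[step_idx] = pulse_drive.get(step_idx, 0.0) + base
                pulse_sec.append(round(tp, 6))

    v = np.zeros(n)
    refr = np.zeros(n, dtype=int)
    x = np.full(n, p.init_resources)  # synaptic resources (excitatory neurons deplete)

    ev_steps: list[int] = []
    ev_electrodes: list[int] = []
    W = culture.weights
    # strengthened pathways: boost outgoing efficacy of neurons under each
    # stimulated input electrode by that pathway's gain
    scale = np.ones(n)
    for _t0, cmd in schedule:
        g = culture.gain(cmd.electrode)
        if g != 1.0:
            under = culture.stim_drive(cmd.electrode) > 0
            scale[under] = np.maximum(scale[under], g)
    if np.any(scale != 1.0):
        # strengthening is confined to the local pathway: inter-quadrant
        # bridge synapses keep their nominal weight
        W = np.where(culture.bridge, W, W * scale[None, :])
    exc = culture.excitatory

    # bucket synapses by conduction delay; spikes deliver into a ring buffer
    delay_values = [int(d) for d in np.unique(culture.delays) if d > 0]
    W_by_delay = [(d, W * (culture.delays == d)) for d in delay_values]
    ring_len = (max(delay_values) if delay_values else 1) + 1
    ring = np.zeros((ring_len, n))

    for step in range(n_steps):
        slot = step % ring_len
        i_total = ring[slot].copy()
        ring[slot] = 0.0
        if step in pulse_drive:
            i_total += pulse_drive[step]
        if p_bg > 0:
            i_total += p.noise_amp * (rng.random(n) < p_bg)
        active = refr <= 0
        v = np.where(active, v * decay + i_total, 0.0)

        spiked = (v >= V_THRESH) & active

        if spiked.any():
            js = np.flatnonzero(spiked)
            rel = np.where(exc[js], x[js], 1.0)
            for d, Wd in W_by_delay:
                ring[(step + d) % ring_len] += Wd[:, js] @ rel
            x[js[exc[js]]] *= 1.0 - u
            v[js] = 0.0
            refr[js] = refr_steps
            rec_idx = culture.electrode_of[js]
            for ji, ei in zip(js, rec_idx):
                if ei >= 0:
                    ev_steps.append(step)
                    ev_electrodes.append(ei)

        x += rec_step * (1.0 - x)
        np.clip(x, 0.0, 1.0, out=x)
        refr -= 1

    rec = culture.recording_electrodes
    times = np.asarray(ev_steps, dtype=float) * (DT_MS / 1000.0)
    labels = np.array([rec[i] for i in ev_electrodes], dtype=object)
    order = np.argsort(times, kind="stable")
    return Raster(
        duration=duration,
        electrodes=labels[order] if len(labels) else labels,
        times=times[order] if len(times) else times,
        stim_marks=[(round(t, 6), cmd.electrode) for t, cmd in schedule],
        pulse_times=sorted(pulse_sec),
        geometry=culture.geometry,
    )


def update_pathway_gain(
    culture: Culture, input_electrode: str, evoked_success: bool
) -> Culture:
    """Ratchet the stimulated pathway's gain on a successful evoked response.

    Gain is multiplied by (1 + pathway_gain_rate) per success, capped at
    ``pathway_gain_cap``; failures leave it unchanged, and gains never fall
    below 1.  Only previously designated inputs may be updated.  The culture
    is updated in place and returned.
    """
    label = electrode_label(*parse_electrode(input_electrode))
    if label not in culture.pathway_gains:
        raise ConfigurationError(f"{label} has not been designated as an input")
    if evoked_success:
        g = culture.pathway_gains[label] * (1.0 + culture.params.pathway_gain_rate)
        culture.pathway_gains[label] = min(g, culture.params.pathway_gain_cap)
    culture.pathway_gains[label] = max(culture.pathway_gains[label], 1.0)
    return culture


def voltage_traces(
    raster: Raster,
    electrodes: Sequence[str],
    sampling_rate: float = 10000.0,
    noise_sd: float = 1.0,
    spike_amplitude: float = 8.0,
    artifact_amplitude: float = 200.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Synthesize extracellular voltage traces from a raster.

    Gaussian noise plus a biphasic (negative-first) waveform at each spike
    time, with a saturating 4 ms artifact transient painted onto *every*
    electrode at each stimulation pulse — the raw material the spike detector
    and artifact filter operate on.
    """
    rng = np.random.default_rng(seed)
    n_samp = int(round(raster.duration * sampling_rate))
    # 1 ms biphasic spike waveform: negative lobe then positive
    t_w = np.arange(int(sampling_rate * 0.001)) / sampling_rate
    wave = -np.sin(np.pi * t_w / 0.001) * np.exp(-t_w / 0.0004) * spike_amplitude
    art_len = int(sampling_rate * ARTIFACT_MS / 1000.0)
    out: dict[str, np.ndarray] = {}
    for e in electrodes:
        label = electrode_label(*parse_electrode(e))
        trace = rng.normal(0.0, noise_sd, size=n_samp)
        for t in raster.spikes_of(label):
            i0 = int(round(t * sampling_rate))
            seg = wave[: max(0, min(len(wave), n_samp - i0))]
            trace[i0 : i0 + len(seg)] += seg
        for tp in raster.pulse_times:
            i0 = int(round(tp * sampling_rate))
            i1 = min(i0 + art_len, n_samp)
            if i0 < n_samp:
                # saturating biphasic transient
                trace[i0:i1] = artifact_amplitude * np.where(
                    (np.arange(i1 - i0) * 2 < art_len), -1.0, 1.0
                )
        out[label] = trace
    return out
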