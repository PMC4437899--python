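"""The closed-loop experimental protocol as executable computation.

Session flow mirrors the bench protocol: probe candidate electrodes with the
standard pair-pulse stimulus on a 30 s cadence until at least two evoke
network firing; pick the most mutually dissimilar responders as *input*
electrodes; for each input, the region responding most strongly becomes its
*output area* and the remaining responders its *other area*.  The robot then
runs 15-minute trials: the bearing to the object is encoded as a stimulus on
input 1 (object to the left) or input 2 (object to the right), the evoked
response is decoded winner-take-all between the two output areas, and the
robot turns accordingly.  Stimulations are at least 20 s apart; trials repeat
over three or more phases separated by short rests, carrying the culture's
pathway gains across phases.

The neural side is simulated event-drivenly: each stimulation (and each
probe) runs the network for a short window around the pulse pair, which is
exact for decoding purposes because the decision depends only on the evoked
response inside that window; between stimulations only the robot moves and
the synaptic state relaxes back to its inter-burst baseline.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    ConfigurationError,
    ProtocolFailure,
    MEAGeometry,
    StimulusCommand,
    electrode_label,
    parse_electrode,
)
from .culture import Culture, simulate, update_pathway_gain
from .robot import ArenaConfig, RobotState, bearing_to_object, reached, required_turn, step
from .signal import EvokedResponse, baseline_corrected_response, responding_set

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolParams",
    "stimulate_once",
    "AreaAssignment",
    "DecisionRecord",
    "TrialLog",
    "ExperimentLog",
    "probe_candidates",
    "select_inputs",
    "assign_areas",
    "encode",
    "decode",
    "run_trial",
    "run_experiment",
    "DEFAULT_CANDIDATES",
]

# default probing candidates: one interior electrode per quadrant
DEFAULT_CANDIDATES = ["r2c2", "r2c7", "r7c2", "r7c7"]


@dataclass(frozen=True)
class ProtocolParams:
    """Tunables of the closed-loop session (times in seconds, angles in degrees)."""

    candidates: tuple[str, ...] = tuple(DEFAULT_CANDIDATES)
    inter_probe_interval: float = 30.0
    probe_repeats: int = 3
    min_network_size: int = 4  # responders needed to call "network firing"
    k_inputs: int = 2
    response_window: float = 0.5  # s, decoding/responder window after the stimulus
    min_spikes: float = 1.0
    stim_period: float = 20.0  # s between stimulations
    trial_duration: float = 900.0  # 15 min
    n_phases: int = 3
    rest_minutes: float = 3.0  # in the 2-4 min range
    deadband_deg: float = 10.0
    turn_step_deg: float = 60.0  # maximum turn per command
    robot_speed: float = 0.02  # m/s between decisions
    wheelbase: float = 0.1  # m
    motion_dt: float = 0.1  # s, kinematic substep between decisions
    plasticity: bool = True
    area_scheme: str = "quadrant"  # 'quadrant' or 'cluster' (contiguous responder cores)
    sim_window_margin: float = 0.55  # s before each pulse pair (>= response window, for the baseline)

    def __post_init__(self):
        if self.inter_probe_interval < 20.0:
            raise ConfigurationError("probe cadence must respect the 20 s refractory gap")
        if self.stim_period < 20.0:
            raise ConfigurationError("stimulations must be at least 20 s apart")
        if self.k_inputs < 2:
            raise ConfigurationError("need at least two input electrodes")

    @property
    def deadband(self) -> float:
        return math.radians(self.deadband_deg)

    @property
    def turn_step(self) -> float:
        return math.radians(self.turn_step_deg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidates"] = list(self.candidates)
        return d


@dataclass
class AreaAssignment:
    """Input electrodes with their output and other areas."""

    inputs: list[str]
    output_area: dict[str, set[str]]
    other_area: dict[str, set[str]]

    def __post_init__(self):
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError("input electrodes must be distinct")
        for e in self.inputs:
            if e not in self.output_area:
                raise ValueError(f"input {e} lacks an output area")
            if self.output_area[e] & self.other_area.get(e, set()):
                raise ValueError(f"output and other areas of {e} overlap")

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "output_area": {k: sorted(v) for k, v in self.output_area.items()},
            "other_area": {k: sorted(v) for k, v in self.other_area.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AreaAssignment":
        return cls(
            inputs=list(d["inputs"]),
            output_area={k: set(v) for k, v in d["output_area"].items()},
            other_area={k: set(v) for k, v in d["other_area"].items()},
        )


@dataclass(frozen=True)
class DecisionRecord:
    time: float
    stimulated_input: str
    decoded: str  # left / right
    required: str  # left / right / none
    correct: bool
    pose: tuple[float, float, float]  # x, y, heading at decision
    tie: bool = False

    def __post_init__(self):
        if self.required != "none" and self.correct != (self.decoded == self.required):
            raise ValueError("correct flag inconsistent with decoded/required")


@dataclass
class TrialLog:
    phase: int
    start_time: float
    end_time: float
    decisions: list[DecisionRecord] = field(default_factory=list)
    pose_track: list[tuple[float, float, float, float]] = field(default_factory=list)
    reach_times: list[float] = field(default_factory=list)  # durations start->reach
    reach_events: list[float] = field(default_factory=list)  # absolute times
    stim_events: list[tuple[float, str]] = field(default_factory=list)
    failure: bool = False

    def validate(self, params: ProtocolParams) -> None:
        if not self.failure:
            if abs((self.end_time - self.start_time) - params.trial_duration) > 1e-6:
                raise ValueError("trial duration does not match the configured length")
        times = [t for t, _ in self.stim_events]
        gaps = np.diff(times)
        if len(gaps) and gaps.min() < params.stim_period - 1e-9:
            raise ValueError("stimulation cadence violated (< configured gap)")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class ExperimentLog:
    seed: int
    culture_params: dict
    protocol_params: dict
    assignment: AreaAssignment
    trials: list[TrialLog] = field(default_factory=list)
    probe_times: list[float] = field(default_factory=list)

    def write_jsonl(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(
                json.dumps(
                    {
                        "type": "header",
                        "seed": self.seed,
                        "culture_params": self.culture_params,
                        "protocol_params": self.protocol_params,
                        "assignment": self.assignment.to_dict(),
                        "probe_times": self.probe_times,
                    }
                )
                + "\n"
            )
            for trial in self.trials:
                fh.write(
                    json.dumps(
                        {
                            "type": "trial",
                            "phase": trial.phase,
                            "start_time": trial.start_time,
                            "end_time": trial.end_time,
                            "failure": trial.failure,
                            "reach_times": trial.reach_times,
                            "reach_events": trial.reach_events,
                            "stim_events": trial.stim_events,
                            "decisions": [asdict(d) for d in trial.decisions],
                        }
                    )
                    + "\n"
                )

    @classmethod
    def read_jsonl(cls, path) -> "ExperimentLog":
        path = Path(path)
        log = None
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                if rec["type"] == "header":
                    log = cls(
                        seed=rec["seed"],
                        culture_params=rec["culture_params"],
                        protocol_params=rec["protocol_params"],
                        assignment=AreaAssignment.from_dict(rec["assignment"]),
                        probe_times=rec.get("probe_times", []),
                    )
                elif rec["type"] == "trial":
                    if log is None:
                        raise ValueError("trial record before header")
                    trial = TrialLog(
                        phase=rec["phase"],
                        start_time=rec["start_time"],
                        end_time=rec["end_time"],
                        failure=rec["failure"],
                        reach_times=rec["reach_times"],
                        reach_events=rec["reach_events"],
                        stim_events=[tuple(x) for x in rec["stim_events"]],
                        decisions=[DecisionRecord(**d) for d in (
                            {**dd, "pose": tuple(dd["pose"])} for dd in rec["decisions"]
                        )],
                    )
                    log.trials.append(trial)
        if log is None:
            raise ValueError(f"{path}: no header record found")
        return log


def _sim_window(params: ProtocolParams, command: StimulusCommand) -> float:
    margin = max(params.sim_window_margin, params.response_window + 0.05)
    return (
        margin
        + command.inter_pulse_interval / 1000.0 * (command.pulse_count - 1)
        + params.response_window
        + 0.05
    )


def stimulate_once(
    culture: Culture, command: StimulusCommand, params: ProtocolParams, seed: int
) -> EvokedResponse:
    """Deliver one stimulus to the culture and return its baseline-corrected
    evoked response (the protocol's unit of measurement)."""
    window = _sim_window(params, command)
    margin = max(params.sim_window_margin, params.response_window + 0.05)
    raster = simulate(culture, window, [(margin, command)], seed=seed)
    return baseline_corrected_response(
        raster,
        margin,
        command.electrode,
        window=params.response_window,
        command=command,
    )


def _probe_once(
    culture: Culture, electrode: str, params: ProtocolParams, seed: int
) -> EvokedResponse:
    return stimulate_once(culture, StimulusCommand(electrode=electrode), params, seed)


def _average_responses(responses: Sequence[EvokedResponse]) -> EvokedResponse:
    first = responses[0]
    counts = {e: 0.0 for e in first.counts}
    for r in responses:
        for e, c in r.counts.items():
            counts[e] += c / len(responses)
    return EvokedResponse(
        stim_time=first.stim_time,
        stim_electrode=first.stim_electrode,
        window=first.window,
        counts=counts,
    )


def probe_candidates(
    culture: Culture,
    candidates: Sequence[str] | None = None,
    params: ProtocolParams | None = None,
    seed: int = 0,
) -> tuple[dict[str, EvokedResponse], list[float]]:
    """Probe candidate electrodes on the configured cadence.

    Each candidate receives ``probe_repeats`` pair-pulse probes; responses are
    averaged per candidate.  Probing stops early once at least two candidates
    evoke network firing (responder set >= ``min_network_size``).  Returns the
    evoked maps and the probe schedule times.  Raises :class:`ProtocolFailure`
    if no candidate evokes firing after the full sweep.
    """
    params = params or ProtocolParams()
    candidates = [
        electrode_label(*parse_electrode(e)) for e in (candidates or params.candidates)
    ]
    if not candidates:
        raise ConfigurationError("candidate list must be non-empty")
    rng = np.random.default_rng(seed)
    maps: dict[str, EvokedResponse] = {}
    probe_times: list[float] = []
    t = 0.0
    n_responsive = 0
    for cand in candidates:
        reps = []
        for _ in range(params.probe_repeats):
            probe_times.append(t)
            t += params.inter_probe_interval
            reps.append(_probe_once(culture, cand, params, int(rng.integers(2**31))))
        maps[cand] = _average_responses(reps)
        if len(responding_set(maps[cand], params.min_spikes)) >= params.min_network_size:
            n_responsive += 1
        if n_responsive >= 2 and len(maps) >= 2:
            break
    if n_responsive == 0:
        raise ProtocolFailure("no candidate electrode evoked network firing")
    return maps, probe_times


def _responsive(maps: dict[str, EvokedResponse], params: ProtocolParams) -> list[str]:
    return [
        e
        for e, r in maps.items()
        if len(responding_set(r, params.min_spikes)) >= params.min_network_size
    ]


def select_inputs(
    maps: dict[str, EvokedResponse],
    k: int = 2,
    params: ProtocolParams | None = None,
) -> list[str]:
    """Choose the k responsive candidates with maximally dissimilar evoked maps.

    Dissimilarity is 1 − Jaccard on responder sets, summed over pairs; ties
    break toward the most physically separated electrodes, then the
    lexicographically smallest (row, col) label combination.
    """
    params = params or ProtocolParams()
    responsive = _responsive(maps, params)
    if len(responsive) < k:
        raise ProtocolFailure(
            f"only {len(responsive)} candidates evoked network firing; need {k}"
        )
    sets = {e: responding_set(maps[e], params.min_spikes) for e in responsive}

    def sort_key(e: str):
        return parse_electrode(e)

    def dissim(a: str, b: str) -> float:
        union = sets[a] | sets[b]
        if not union:
            return 0.0
        return 1.0 - len(sets[a] & sets[b]) / len(union)

    def spread(combo) -> float:
        # secondary criterion: physical separation of the stimulation sites
        pts = [np.array(parse_electrode(e), dtype=float) for e in combo]
        return sum(
            float(np.hypot(*(p - q)))
            for p, q in itertools.combinations(pts, 2)
        )

    best = None
    best_key = None
    for combo in itertools.combinations(sorted(responsive, key=sort_key), k):
        score = sum(dissim(a, b) for a, b in itertools.combinations(combo, 2))
        key = (round(score, 9), round(spread(combo), 9))
        if best_key is None or key > best_key:
            best, best_key = combo, key
    return list(best)


def _cluster_areas(responders: set[str], geometry: MEAGeometry) -> list[set[str]]:
    """Spatially contiguous clusters (4-neighborhood on the grid) of responders."""
    remaining = set(responders)
    clusters = []
    while remaining:
        seed_e = min(remaining, key=parse_electrode)
        stack = [seed_e]
        comp = set()
        remaining.discard(seed_e)
        while stack:
            e = stack.pop()
            comp.add(e)
            r, c = parse_electrode(e)
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                nb = electrode_label(rr, cc)
                if nb in remaining:
                    remaining.discard(nb)
                    stack.append(nb)
        clusters.append(comp)
    return clusters


def assign_areas(
    maps: dict[str, EvokedResponse],
    inputs: Sequence[str],
    geometry: MEAGeometry,
    area_scheme: str = "quadrant",
    params: ProtocolParams | None = None,
) -> AreaAssignment:
    """Assign each input its output area (strongest responding region) and other area.

    Under the 'quadrant' scheme the candidate areas are the four quadrants;
    under 'cluster' (for random cultures without physical compartments) they
    are contiguous clusters of responding electrodes.  Two inputs may not
    share an output area: on collision the later input takes its next-best
    area (logged).
    """
    params = params or ProtocolParams()
    if area_scheme not in ("quadrant", "cluster"):
        raise ConfigurationError(f"unknown area scheme {area_scheme!r}")
    responders_of: dict[str, set[str]] = {}
    areas_of: dict[str, list[set[str]]] = {}
    for inp in inputs:
        responders = responding_set(maps[inp], params.min_spikes)
        responders_of[inp] = responders
        if not responders:
            raise ProtocolFailure(f"all areas silent for input {inp}")
        if area_scheme == "quadrant":
            areas = [set(geometry.quadrant_electrodes(q)) - {inp} for q in (1, 2, 3, 4)]
        else:
            # without physical compartments the whole dish tends to respond;
            # candidate areas are contiguous "hot cores" — responders at
            # >= half the input's peak evoked count — which stay input-specific
            peak = max(maps[inp].counts.values())
            thr = max(params.min_spikes, 0.5 * peak)
            core = {e for e, c in maps[inp].counts.items() if c >= thr}
            areas = [c - {inp} for c in _cluster_areas(core or responders, geometry)]
        areas_of[inp] = [a for a in areas if a]
    # iterative greedy: the strongest remaining (input, area) claim wins each
    # round; electrodes already claimed are subtracted from later areas, so a
    # collision pushes the weaker input to its next-best (remaining) region
    output_area: dict[str, set[str]] = {}
    taken: set[str] = set()
    order = {inp: i for i, inp in enumerate(inputs)}
    while len(output_area) < len(inputs):
        best = None
        for inp in inputs:
            if inp in output_area:
                continue
            for a_idx, area in enumerate(areas_of[inp]):
                avail = area - taken
                if not avail:
                    continue
                mean = maps[inp].mean_count(avail)
                if mean == 0 and not (avail & responders_of[inp]):
                    continue
                key = (-mean, a_idx, order[inp])
                if best is None or key < best[0]:
                    best = (key, inp, avail, area)
        if best is None:
            missing = [inp for inp in inputs if inp not in output_area]
            raise ProtocolFailure(f"no available responsive area for inputs {missing}")
        _key, inp, avail, area = best
        if avail != area:
            logger.info("output-area collision for input %s; assigned remainder", inp)
        output_area[inp] = avail
        taken |= avail
    other_area = {
        inp: responders_of[inp] - output_area[inp] - {inp} for inp in inputs
    }
    return AreaAssignment(inputs=list(inputs), output_area=output_area, other_area=other_area)


def encode(
    bearing: float, assignment: AreaAssignment, deadband: float = math.radians(10.0)
) -> StimulusCommand | None:
    """Map a signed bearing to a pair-pulse command: left -> input 1, right -> input 2."""
    if len(assignment.inputs) < 2:
        raise ConfigurationError("assignment must carry at least two inputs")
    if bearing > deadband:
        return StimulusCommand(electrode=assignment.inputs[0])
    if bearing < -deadband:
        return StimulusCommand(electrode=assignment.inputs[1])
    return None


def decode(
    response: EvokedResponse,
    assignment: AreaAssignment,
    rng: np.random.Generator | None = None,
) -> tuple[str, bool]:
    """Winner-take-all between the two inputs' output areas.

    Compares mean evoked count per electrode; input 1's area winning decodes
    'left', input 2's 'right'.  Exact ties (including the all-silent case)
    are broken by a uniform draw from ``rng``; returns (direction, was_tie).
    """
    in1, in2 = assignment.inputs[0], assignment.inputs[1]
    m1 = response.mean_count(assignment.output_area[in1])
    m2 = response.mean_count(assignment.output_area[in2])
    if m1 > m2:
        return "left", False
    if m2 > m1:
        return "right", False
    rng = rng or np.random.default_rng()
    direction = "left" if rng.random() < 0.5 else "right"
    logger.debug("decode tie (both areas %.3f); drew %s", m1, direction)
    return direction, True


def _direction_of_input(assignment: AreaAssignment, electrode: str) -> str:
    return "left" if electrode == assignment.inputs[0] else "right"


def run_trial(
    culture: Culture,
    assignment: AreaAssignment,
    arena: ArenaConfig,
    params: ProtocolParams,
    rng: np.random.Generator,
    phase: int = 0,
    start_time: float = 0.0,
    start_pose: RobotState | None = None,
    decoder: str = "culture",
) -> tuple[TrialLog, RobotState]:
    """Run one 15-minute closed-loop trial; returns the log and final pose.

    ``decoder`` selects the command source: 'culture' (stimulate the network
    and decode its evoked response), 'oracle' (always the required turn; an
    upper-bound harness), or 'random' (uniform coin without stimulation; the
    chance-level harness).
    """
    if decoder not in ("culture", "oracle", "random"):
        raise ConfigurationError(f"unknown decoder {decoder!r}")
    start_pose = start_pose or arena.start_corners[0]
    state = start_pose
    log = TrialLog(phase=phase, start_time=start_time, end_time=start_time + params.trial_duration)
    t = 0.0  # time within trial
    clock_start = 0.0  # start of current reach attempt
    v = params.robot_speed
    n_epochs = int(params.trial_duration // params.stim_period)
    log.pose_track.append((start_time, state.x, state.y, state.heading))

    corners = arena.start_corners
    corner_idx = corners.index(start_pose) if start_pose in corners else 0

    def advance(until: float):
        nonlocal state, t, clock_start, corner_idx
        while t < until - 1e-9:
            dt = min(params.motion_dt, until - t)
            state = step(state, v, v, dt, params.wheelbase, arena)
            t += dt
            if reached(state, arena):
                log.reach_times.append(t - clock_start)
                log.reach_events.append(start_time + t)
                # resettle at the next start corner and restart the clock
                corner_idx = (corner_idx + 1) % len(corners)
                state = corners[corner_idx]
                clock_start = t
        t = until  # keep epoch bookkeeping exact despite substep rounding
        log.pose_track.append((start_time + t, state.x, state.y, state.heading))

    for k in range(1, n_epochs + 1):
        advance(k * params.stim_period)
        if t >= params.trial_duration - 1e-9:
            break
        bearing = bearing_to_object(state, arena)
        required = required_turn(bearing, params.deadband)
        if required == "none":
            continue
        if decoder == "oracle":
            decoded, tie = required, False
        elif decoder == "random":
            decoded, tie = ("left" if rng.random() < 0.5 else "right"), False
        else:
            cmd = encode(bearing, assignment, params.deadband)
            assert cmd is not None
            response = stimulate_once(culture, cmd, params, int(rng.integers(2**31)))
            decoded, tie = decode(response, assignment, rng)
            log.stim_events.append((start_time + t, cmd.electrode))
            if params.plasticity:
                success = decoded == _direction_of_input(assignment, cmd.electrode)
                update_pathway_gain(culture, cmd.electrode, success)
        correct = decoded == required
        stim_input = (
            assignment.inputs[0] if required == "left" else assignment.inputs[1]
        )
        log.decisions.append(
            DecisionRecord(
                time=start_time + t,
                stimulated_input=stim_input,
                decoded=decoded,
                required=required,
                correct=correct,
                pose=(state.x, state.y, state.heading),
                tie=tie,
            )
        )
        # the camera supplies the bearing magnitude; the decoded direction
        # chooses the sign; the turn is capped at turn_step per command
        magnitude = min(abs(bearing), params.turn_step)
        turn = magnitude if decoded == "left" else -magnitude
        state = RobotState(state.x, state.y, state.heading + turn, state.speed)
    advance(params.trial_duration)
    log.validate(params)
    return log, state


def run_experiment(
    culture: Culture,
    params: ProtocolParams | None = None,
    arena: ArenaConfig | None = None,
    seed: int = 0,
    decoder: str = "culture",
) -> ExperimentLog:
    """Probe, select inputs, assign areas, then run the multi-phase closed loop.

    Pathway gains (the slow plasticity state) carry across phases; rests
    advance simulated time only.
    """
    params = params or ProtocolParams()
    arena = arena or ArenaConfig()
    rng = np.random.default_rng(seed)
    maps, probe_times = probe_candidates(culture, params.candidates, params, seed=int(rng.integers(2**31)))
    inputs = select_inputs(maps, params.k_inputs, params)
    assignment = assign_areas(maps, inputs, culture.geometry, params.area_scheme, params)
    culture.designate_inputs(inputs)
    log = ExperimentLog(
        seed=seed,
        culture_params=culture.params.to_dict(),
        protocol_params=params.to_dict(),
        assignment=assignment,
        probe_times=probe_times,
    )
    t0 = probe_times[-1] + params.inter_probe_interval if probe_times else 0.0
    pose = arena.start_corners[0]
    for phase in range(1, params.n_phases + 1):
        trial, pose = run_trial(
            culture,
            assignment,
            arena,
            params,
            rng,
            phase=phase,
            start_time=t0,
            start_pose=arena.start_corners[0],
            decoder=decoder,
        )
        log.trials.append(trial)
        t0 = trial.end_time + params.rest_minutes * 60.0
    return log
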