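"""Recording-side computation: spike detection, artifact blanking, evoked
responses, responder sets, and network-burst detection.

Spike detection uses the standard MEA convention — negative threshold
crossings at k times the robust noise SD (median absolute deviation / 0.6745)
with a 1 ms refractory lockout.  Stimulation artifacts are handled by
blanking a short window after every pulse; the default 4 ms is shorter than
the 50 ms pair-pulse interval, so both pulses of a pair are blanked
independently and the inter-pulse response is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MEAGeometry, Raster, StimulusCommand, electrode_label, parse_electrode

__all__ = [
    "EvokedResponse",
    "BurstInterval",
    "detect_spikes",
    "blank_artifacts",
    "evoked_response",
    "responding_set",
    "detect_bursts",
    "DEFAULT_BLANK_MS",
    "DEFAULT_RESPONSE_WINDOW_S",
]

DEFAULT_BLANK_MS = 4.0
DEFAULT_RESPONSE_WINDOW_S = 2.0
REFRACTORY_S = 0.001


@dataclass(frozen=True)
class EvokedResponse:
    """Per-electrode spike counts in a post-stimulus window (artifact-blanked).

    ``counts`` maps every recording electrode except the stimulated one to its
    spike count in (stim_time + blank, stim_time + window].  Counts may be
    fractional when averaged over repeated probes.
    """

    stim_time: float
    stim_electrode: str
    window: tuple[float, float]  # (start offset, end offset) s after first pulse
    counts: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("evoked counts must be non-negative")
        if self.stim_electrode in self.counts:
            raise ValueError("stimulated electrode must be excluded from counts")

    def mean_count(self, electrodes) -> float:
        """Mean count per electrode over a subset (0 if the subset is empty)."""
        els = [e for e in electrodes if e != self.stim_electrode]
        if not els:
            return 0.0
        return float(np.mean([self.counts.get(e, 0.0) for e in els]))


@dataclass(frozen=True)
class BurstInterval:
    start: float
    end: float
    electrodes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("burst end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_spikes(
    trace: np.ndarray, sampling_rate: float, threshold_k: float = 5.0
) -> np.ndarray:
    """Detect negative-going threshold crossings in a single-electrode trace.

    Threshold is −threshold_k × (median(|x − median(x)|)/0.6745); a crossing is
    a sample below threshold whose predecessor was at or above it.  A 1 ms
    lockout suppresses re-triggering on the same deflection.  Returns spike
    times in seconds.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    med = np.median(trace)
    noise_sd = np.median(np.abs(trace - med)) / 0.6745
    if noise_sd == 0:
        return np.empty(0, dtype=float)
    thr = -threshold_k * noise_sd + med
    below = trace < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        crossings = np.insert(crossings, 0, 0)
    lockout = max(1, int(round(REFRACTORY_S * sampling_rate)))
    kept = []
    last = -lockout - 1
    for idx in crossings:
        if idx - last > lockout:
            kept.append(idx)
            last = idx
    return np.asarray(kept, dtype=float) / sampling_rate


def blank_artifacts(
    spike_times: np.ndarray, pulse_times, blank_window_ms: float = DEFAULT_BLANK_MS
) -> np.ndarray:
    """Drop spikes falling within [pulse, pulse + blank_window] of any pulse."""
    if blank_window_ms < 0:
        raise ValueError("blank window must be non-negative")
    spike_times = np.asarray(spike_times, dtype=float)
    if blank_window_ms == 0 or spike_times.size == 0:
        return spike_times.copy()
    w = blank_window_ms / 1000.0
    keep = np.ones(spike_times.shape, dtype=bool)
    for p in pulse_times:
        keep &= ~((spike_times >= p) & (spike_times <= p + w))
    return spike_times[keep]


def evoked_response(
    raster: Raster,
    stim_time: float,
    stim_electrode: str,
    window: float = DEFAULT_RESPONSE_WINDOW_S,
    blank_ms: float = DEFAULT_BLANK_MS,
    command: StimulusCommand | None = None,
) -> EvokedResponse:
    """Count spikes per recording electrode in the post-stimulus window.

    Spikes within the artifact-blanking window after each pulse are removed
    first; counting then runs over (stim_time + blank, stim_time + window].
    Pulse times are taken from the raster's recorded pulses when available,
    otherwise from ``command`` (default pair-pulse timing).
    """
    stim_electrode = electrode_label(*parse_electrode(stim_electrode))
    if stim_time + window > raster.duration + 1e-9:
        raise ValueError("response window extends past the session duration")
    mark_times = [t for t, _ in raster.stim_marks]
    if mark_times and not any(abs(stim_time - t) < 1e-9 for t in mark_times):
        warnings.warn(
            f"stim_time {stim_time} not among recorded stimulation marks",
            stacklevel=2,
        )
    if raster.pulse_times:
        pulses = [p for p in raster.pulse_times if stim_time - 1e-9 <= p <= stim_time + window]
        if not pulses:
            pulses = [stim_time]
    else:
        cmd = command or StimulusCommand(electrode=stim_electrode)
        pulses = cmd.pulse_times(stim_time)
    blank_s = blank_ms / 1000.0
    counts: dict[str, float] = {
        e: 0.0 for e in raster.geometry.recording_electrodes if e != stim_electrode
    }
    lo, hi = stim_time + blank_s, stim_time + window
    sel = (raster.times > lo) & (raster.times <= hi)
    for e, t in zip(raster.electrodes[sel], raster.times[sel]):
        if e == stim_electrode:
            continue
        if any(p <= t <= p + blank_s for p in pulses):
            continue
        counts[e] += 1.0
    return EvokedResponse(
        stim_time=stim_time,
        stim_electrode=stim_electrode,
        window=(blank_s, window),
        counts=counts,
    )


def baseline_corrected_response(
    raster: Raster,
    stim_time: float,
    stim_electrode: str,
    window: float = DEFAULT_RESPONSE_WINDOW_S,
    blank_ms: float = DEFAULT_BLANK_MS,
    command: StimulusCommand | None = None,
) -> EvokedResponse:
    """Evoked response with the pre-stimulus baseline subtracted per electrode.

    Counts spikes in the post-stimulus window as :func:`evoked_response`, then
    subtracts each electrode's count in the immediately preceding window of
    the same length (clipped at zero).  This separates genuinely evoked
    activity from ongoing spontaneous bursting, which otherwise masquerades
    as a reliable "response" on tonically active regions.  Requires
    ``stim_time >= window``.
    """
    if stim_time < window - 1e-9:
        raise ValueError("need a pre-stimulus window of the same length as the response window")
    post = evoked_response(raster, stim_time, stim_electrode, window, blank_ms, command)
    lo, hi = stim_time - window, stim_time
    sel = (raster.times > lo) & (raster.times <= hi)
    pre: dict[str, float] = {e: 0.0 for e in post.counts}
    for e in raster.electrodes[sel]:
        if e in pre:
            pre[e] += 1.0
    counts = {e: max(0.0, c - pre[e]) for e, c in post.counts.items()}
    return EvokedResponse(
        stim_time=post.stim_time,
        stim_electrode=post.stim_electrode,
        window=post.window,
        counts=counts,
    )


def responding_set(response: EvokedResponse, min_spikes: float = 1) -> set[str]:
    """Electrodes whose evoked count reaches min_spikes."""
    if min_spikes < 1:
        raise ValueError("min_spikes must be >= 1")
    return {e for e, c in response.counts.items() if c >= min_spikes}


def detect_bursts(
    raster: Raster,
    bin_s: float = 0.1,
    rate_threshold: float = 0.5,
) -> list[BurstInterval]:
    """Find network bursts as runs of bins with high population participation.

    Participation in a bin is the fraction of the session's active electrodes
    (those with any spike at all) that fire in that bin; consecutive bins
    exceeding ``rate_threshold`` merge into maximal intervals.
    """
    if bin_s <= 0:
        raise ValueError("bin must be positive")
    active = sorted(raster.active_electrodes())
    if not active or raster.duration == 0:
        return []
    n_bins = int(np.ceil(raster.duration / bin_s))
    idx = {e: i for i, e in enumerate(active)}
    fired = np.zeros((n_bins, len(active)), dtype=bool)
    bins = np.minimum((raster.times / bin_s).astype(int), n_bins - 1)
    for b, e in zip(bins, raster.electrodes):
        fired[b, idx[e]] = True
    participation = fired.sum(axis=1) / len(active)
    hot = participation > rate_threshold
    bursts: list[BurstInterval] = []
    i = 0
    while i < n_bins:
        if hot[i]:
            j = i
            while j + 1 < n_bins and hot[j + 1]:
                j += 1
            members = frozenset(
                active[k] for k in np.flatnonzero(fired[i : j + 1].any(axis=0))
            )
            bursts.append(
                BurstInterval(
                    start=i * bin_s,
                    end=min((j + 1) * bin_s, raster.duration),
                    electrodes=members,
                )
            )
            i = j + 1
        else:
            i += 1
    return bursts
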