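"""Analysis statistics for closed-loop MEA-robot sessions.

Covers the response-specificity measures (redundancy ratio between the
responder sets of two stimuli, output-area vs other-area evoked rates,
evoked-electrode fractions), the robot performance metrics (correct-turning
percentage per direction, time-to-reach), phase-wise evolution, and the
two-sample Kolmogorov–Smirnov test used for significance throughout
(P < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .protocol import AreaAssignment, ExperimentLog, TrialLog
from .signal import EvokedResponse, responding_set

__all__ = [
    "RedundancyRatio",
    "PerformanceSummary",
    "redundancy_ratio",
    "compartment_rates",
    "evoked_fraction",
    "performance",
    "ks_two_sample",
    "phase_evolution",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class RedundancyRatio:
    """Overlap of the responder sets of two different stimuli.

    ratio = |A ∩ B| / |A ∪ B| — electrodes responding to both stimuli over
    all electrodes responding to either; ``defined`` is False when neither
    stimulus evoked any responder.  Symmetric in the two stimuli.
    """

    stimuli: tuple[str, str]
    shared: int
    total: int
    ratio: float
    defined: bool = True


def redundancy_ratio(
    responders_a: Iterable[str],
    responders_b: Iterable[str],
    stimuli: tuple[str, str] = ("A", "B"),
    denominator: str = "union",
    n_recording: int = 59,
) -> RedundancyRatio:
    """Redundancy between two responder sets.

    ``denominator='union'`` (default) uses electrodes responding to either
    stimulus; ``'all'`` uses the full recording-electrode count instead.
    """
    a, b = set(responders_a), set(responders_b)
    shared = len(a & b)
    if denominator == "union":
        total = len(a | b)
    elif denominator == "all":
        total = n_recording
    else:
        raise ValueError(f"unknown denominator scheme {denominator!r}")
    if total == 0:
        return RedundancyRatio(stimuli, shared, total, float("nan"), defined=False)
    return RedundancyRatio(stimuli, shared, total, shared / total)


def compartment_rates(
    response: EvokedResponse,
    assignment: AreaAssignment,
    input_electrode: str,
    per_second: bool = False,
) -> tuple[float, float]:
    """Mean evoked count per electrode in the input's output vs other area.

    With ``per_second`` the counts are divided by the response-window length.
    Empty compartments yield NaN (undefined, not zero).
    """
    if input_electrode not in assignment.output_area:
        raise KeyError(f"{input_electrode} is not an assigned input")
    out_area = assignment.output_area[input_electrode]
    oth_area = assignment.other_area.get(input_electrode, set())
    span = response.window[1] - response.window[0]
    scale = 1.0 / span if per_second else 1.0

    def rate(area: set[str]) -> float:
        area = {e for e in area if e != response.stim_electrode}
        if not area:
            return float("nan")
        return response.mean_count(area) * scale

    return rate(out_area), rate(oth_area)


def evoked_fraction(
    response: EvokedResponse, area: Iterable[str], min_spikes: float = 1
) -> float:
    """Percentage of area electrodes showing an evoked response."""
    area = {e for e in area if e != response.stim_electrode}
    if not area:
        raise ValueError("output area must be non-empty")
    responders = responding_set(response, min_spikes)
    return 100.0 * len(responders & area) / len(area)


@dataclass
class PerformanceSummary:
    """Correct-turning percentages and reach times, pooled and per phase."""

    per_direction: dict[str, float | None]  # 'left'/'right' -> % or None if no decisions
    joint: float | None  # product of the two per-direction fractions, as %
    times_to_reach: list[float]
    n_decisions: int
    n_correct: int
    phases: pd.DataFrame = field(default_factory=pd.DataFrame)

    def minimum_direction(self) -> float | None:
        vals = [v for v in self.per_direction.values() if v is not None]
        return min(vals) if vals else None


def _direction_pct(decisions, direction: str) -> float | None:
    rel = [d for d in decisions if d.required == direction]
    if not rel:
        return None
    return 100.0 * sum(d.correct for d in rel) / len(rel)


def performance(log: ExperimentLog | Sequence[TrialLog]) -> PerformanceSummary:
    """Summarize an experiment: correct-turning % per direction and reach times.

    Per-direction percentages count only decisions whose geometrically
    required turn is that direction; a direction with no decisions is
    reported as None (undefined), never as 0.  The joint value is the product
    of the two per-direction fractions (both-direction correctness).
    """
    trials = log.trials if isinstance(log, ExperimentLog) else list(log)
    all_dec = [d for t in trials for d in t.decisions]
    if not all_dec:
        raise ValueError("no decisions in the supplied logs")
    rows = []
    for t in trials:
        rows.append(
            {
                "phase": t.phase,
                "n_decisions": len(t.decisions),
                "correct_left_pct": _direction_pct(t.decisions, "left"),
                "correct_right_pct": _direction_pct(t.decisions, "right"),
                "n_reaches": len(t.reach_times),
                "mean_time_to_reach_s": float(np.mean(t.reach_times)) if t.reach_times else np.nan,
                "sd_time_to_reach_s": float(np.std(t.reach_times, ddof=1))
                if len(t.reach_times) > 1
                else np.nan,
            }
        )
    phases = pd.DataFrame(rows).set_index("phase")
    per_dir = {d: _direction_pct(all_dec, d) for d in ("left", "right")}
    joint = None
    if all(v is not None for v in per_dir.values()):
        joint = per_dir["left"] * per_dir["right"] / 100.0
    return PerformanceSummary(
        per_direction=per_dir,
        joint=joint,
        times_to_reach=[tt for t in trials for tt in t.reach_times],
        n_decisions=len(all_dec),
        n_correct=sum(d.correct for d in all_dec),
        phases=phases,
    )


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test: returns (D, p).

    Uses the exact null distribution for small samples and the asymptotic
    Kolmogorov distribution otherwise; identical constant samples give
    D = 0, p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples must have at least 2 observations")
    if np.array_equal(np.sort(x), np.sort(y)) and len(set(x)) <= 1:
        return 0.0, 1.0
    res = sps.ks_2samp(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def phase_evolution(
    log: ExperimentLog | Sequence[TrialLog],
) -> tuple[pd.DataFrame, dict]:
    """Per-phase performance table plus first-vs-last comparison.

    Returns the phase table (means ± SD of time-to-reach, correct % per
    direction) and a dict with monotonicity flags and the K-S test of
    first-phase vs last-phase reach times (when both phases logged >= 2
    reaches).
    """
    trials = log.trials if isinstance(log, ExperimentLog) else list(log)
    if len(trials) < 2:
        raise ValueError("phase evolution needs at least 2 phases")
    summary = performance(trials)
    table = summary.phases
    first, last = trials[0], trials[-1]

    def seq_flags(col: str, increasing: bool) -> bool:
        vals = table[col].dropna().tolist()
        if len(vals) < 2:
            return False
        diffs = np.diff(vals)
        return bool(np.all(diffs >= 0) if increasing else np.all(diffs <= 0))

    flags = {
        "time_to_reach_decreasing": seq_flags("mean_time_to_reach_s", increasing=False),
        "correct_left_increasing": seq_flags("correct_left_pct", increasing=True),
        "correct_right_increasing": seq_flags("correct_right_pct", increasing=True),
    }
    ks = None
    if len(first.reach_times) >= 2 and len(last.reach_times) >= 2:
        d, p = ks_two_sample(first.reach_times, last.reach_times)
        ks = {"D": d, "p": p, "significant": p < SIGNIFICANCE_LEVEL}
    return table, {"flags": flags, "first_vs_last_reach_ks": ks}
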