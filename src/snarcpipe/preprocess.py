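"""Trial-filtering cascade and participant-level exclusion rules.

Filtering order per participant x task: (1) incorrect responses, (2) RTs
outside the 200-1500 ms window, (3) iterative trimming of RTs outside
mean +/- 3 SD of the currently retained trials, repeated until the retained
set no longer changes. Mean and SD are pooled over the whole task (blocks and
digits together); SD uses the n-1 denominator.

Participants are excluded when fewer than 75% of a task's trials survive the
cascade, or when any digit x response-side cell ends up empty in either task.
The 75% denominator is all experimental trials of the task, so losses from
all three stages count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from snarcpipe.simulate import DIGITS, TASKS

DEFAULT_RT_WINDOW = (200.0, 1500.0)
DEFAULT_SD_MULTIPLIER = 3.0
DEFAULT_RETENTION_THRESHOLD = 0.75
_MAX_SD_ITERATIONS = 100


@dataclass
class FilterReport:
    n_input: int
    n_removed_incorrect: int
    n_removed_window: int
    n_removed_sd: int
    n_retained: int
    retention_fraction: float
    sd_iterations: int

    def __post_init__(self) -> None:
        total = (
            self.n_removed_incorrect
            + self.n_removed_window
            + self.n_removed_sd
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(
                f"stage counts {total} do not sum to n_input {self.n_input}"
            )


@dataclass
class ExclusionDecision:
    participant_id: str
    excluded: bool
    reason: str  # {"low_retention", "empty_cell", "none"}

    def __post_init__(self) -> None:
        if self.excluded != (self.reason != "none"):
            raise ValueError("excluded must be True iff reason != 'none'")


def filter_trials(
    trials: pd.DataFrame,
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three-stage filter to one participant's trials in one task."""
    n_input = len(trials)
    if n_input == 0:
        return trials.copy(), FilterReport(0, 0, 0, 0, 0, 0.0, 0)
    if trials["participant_id"].nunique() > 1 or trials["task"].nunique() > 1:
        raise ValueError("filter_trials expects one participant and one task")
    lo, hi = rt_window
    if not lo < hi:
        raise ValueError("rt_window: lower bound must be below upper bound")

    correct = trials[trials["correct"].astype(bool)]
    n_removed_incorrect = n_input - len(correct)

    in_window = correct[(correct["rt_ms"] >= lo) & (correct["rt_ms"] <= hi)]
    n_removed_window = len(correct) - len(in_window)

    retained = in_window
    sd_iterations = 0
    n_removed_sd = 0
    while len(retained) > 0 and sd_iterations < _MAX_SD_ITERATIONS:
        sd_iterations += 1
        rts = retained["rt_ms"].to_numpy(dtype=float)
        if len(rts) < 2:
            break
        mean = rts.mean()
        sd = rts.std(ddof=1)
        if sd == 0.0:
            break
        keep = np.abs(rts - mean) <= sd_multiplier * sd
        if keep.all():
            break
        n_removed_sd += int((~keep).sum())
        retained = retained[keep]

    n_retained = len(retained)
    report = FilterReport(
        n_input=n_input,
        n_removed_incorrect=n_removed_incorrect,
        n_removed_window=n_removed_window,
        n_removed_sd=n_removed_sd,
        n_retained=n_retained,
        retention_fraction=n_retained / n_input,
        sd_iterations=sd_iterations,
    )
    return retained.copy(), report


def _has_empty_cell(task_trials: pd.DataFrame) -> bool:
    counts = task_trials.groupby(["digit", "response_side"]).size()
    for d in DIGITS:
        for side in ("left", "right"):
            if counts.get((d, side), 0) == 0:
                return True
    return False


def exclude_participants(
    retained: pd.DataFrame,
    reports: Mapping[tuple[str, str], FilterReport],
    retention_threshold: float = DEFAULT_RETENTION_THRESHOLD,
    tasks: Sequence[str] = TASKS,
) -> list[ExclusionDecision]:
    """Decide, per participant, whether to keep them for slope estimation.

    ``retained`` holds the post-filter trials of all participants (both
    tasks); ``reports`` maps ``(participant_id, task)`` to the corresponding
    filter report. Low retention is checked before empty cells; a missing
    task counts as an empty cell.
    """
    if not 0.0 <= retention_threshold <= 1.0:
        raise ValueError("retention_threshold: must lie in [0, 1]")
    participants = sorted({pid for pid, _ in reports.keys()})
    if len(retained):
        participants = sorted(set(participants) | set(retained["participant_id"].unique()))
    decisions = []
    for pid in participants:
        reason = "none"
        for task in tasks:
            rep = reports.get((pid, task))
            if rep is not None and rep.retention_fraction < retention_threshold:
                reason = "low_retention"
                break
        if reason == "none":
            for task in tasks:
                rep = reports.get((pid, task))
                if rep is None:
                    reason = "empty_cell"
                    break
                sub = retained[
                    (retained["participant_id"] == pid) & (retained["task"] == task)
                ]
                if len(sub) == 0 or _has_empty_cell(sub):
                    reason = "empty_cell"
                    break
        decisions.append(
            ExclusionDecision(
                participant_id=pid, excluded=reason != "none", reason=reason
            )
        )
    return decisions
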