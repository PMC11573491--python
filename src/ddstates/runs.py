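"""Run segmentation and the eight peri-choice trial types.

A *run* is three or more consecutive choice-trial responses on the same lever
(forced trials are ignored for continuity — the animal keeps choosing the
lever despite being exposed to the other one on forced trials). The fourth
choice trial after the run's start classifies it: choosing the opposite lever
is a **Change** run, staying is a **Fail-to-Change** run. Crossing lever
(IM/DEL), outcome (Change/Fail-to-Change) and trial position (3rd/4th) gives
the eight trial types the ensemble analysis aligns to.

Runs are *maximal-anchored*: within a maximal same-lever streak of length
L >= 3 exactly one run is emitted, anchored at the streak's first three
choices. A sliding variant (one run per 3-choice window within a streak) is
available via ``mode="sliding"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .task import DELAY, SessionRecord

logger = logging.getLogger(__name__)

CHANGE = "Change"
FAIL_TO_CHANGE = "FtC"
LEVER_LABELS = {"immediate": "IM", "delay": "DEL"}

#: The eight peri-choice trial types (lever x outcome x trial position).
TRIAL_TYPES = tuple(
    f"{lever}-{outcome}-T{pos}"
    for lever in ("IM", "DEL")
    for outcome in (CHANGE, FAIL_TO_CHANGE)
    for pos in (3, 4)
)


@dataclass
class RunRecord:
    """One classified run: its lever, length, outcome and trials 3/4."""

    lever: str  # {"IM", "DEL"}
    start_choice_index: int  # index into the session's choice-trial sequence (0-based)
    length: int  # choices in the maximal streak
    outcome: str  # {"Change", "FtC"}
    trial3_id: int  # session trial_index of the 3rd consecutive choice
    trial4_id: int  # session trial_index of the next choice trial

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("a run needs at least three consecutive choices")
        if self.outcome not in (CHANGE, FAIL_TO_CHANGE):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def segment_lever_sequence(
    levers: Sequence[str], mode: str = "anchored"
) -> list[tuple[int, int, str]]:
    """Segment a bare lever sequence into runs.

    Parameters
    ----------
    levers : sequence of lever labels (any hashable; e.g. "IM"/"DEL")
    mode : "anchored" (one run per maximal streak, at its first three
        choices) or "sliding" (every 3-choice window inside a streak).

    Returns
    -------
    list of ``(start_index, streak_length, outcome)`` where ``start_index``
    is the position of the run's first choice and the fourth trial is the
    choice at ``start_index + 3``. Streaks without a fourth choice trial are
    unclassified and omitted (logged).
    """
    if mode not in ("anchored", "sliding"):
        raise ValueError("mode must be 'anchored' or 'sliding'")
    n = len(levers)
    out: list[tuple[int, int, str]] = []
    i = 0
    while i < n:
        j = i
        while j < n and levers[j] == levers[i]:
            j += 1
        streak = j - i
        if streak >= 3:
            starts = [i] if mode == "anchored" else [s for s in range(i, j - 2)]
            for s in starts:
                fourth = s + 3
                if fourth >= n:
                    logger.info(
                        "run at choice %d reached end of session without a 4th choice; excluded", s
                    )
                    continue
                outcome = FAIL_TO_CHANGE if levers[fourth] == levers[s] else CHANGE
                out.append((s, streak, outcome))
        i = j
    return out


def segment_runs(session: SessionRecord, mode: str = "anchored") -> list[RunRecord]:
    """Detect runs over a session's choice trials (forced trials ignored)."""
    choices = session.choice_trials()
    levers = [LEVER_LABELS[tr.chosen_lever] for tr in choices]
    records = []
    for start, streak, outcome in segment_lever_sequence(levers, mode=mode):
        records.append(
            RunRecord(
                lever=levers[start],
                start_choice_index=start,
                length=streak,
                outcome=outcome,
                trial3_id=choices[start + 2].trial_index,
                trial4_id=choices[start + 3].trial_index,
            )
        )
    return records


def trial_type_label(run: RunRecord, which: int) -> str:
    """Map a classified run and a trial position (3 or 4) to one of the
    eight trial-type labels, e.g. ``DEL-Change-T3``."""
    if which not in (3, 4):
        raise ValueError("which must be 3 or 4")
    return f"{run.lever}-{run.outcome}-T{which}"


def run_type(run: RunRecord) -> str:
    """Lever x outcome label without the trial position, e.g. ``IM-FtC``."""
    return f"{run.lever}-{run.outcome}"


def runs_table(session: SessionRecord, runs: list[RunRecord]) -> pd.DataFrame:
    """Tidy table of runs keyed to the session (one row per run)."""
    return pd.DataFrame(
        {
            "session_id": session.session_id,
            "run_id": range(len(runs)),
            "lever": [r.lever for r in runs],
            "outcome": [r.outcome for r in runs],
            "length": [r.length for r in runs],
            "trial3_id": [r.trial3_id for r in runs],
            "trial4_id": [r.trial4_id for r in runs],
        }
    )
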