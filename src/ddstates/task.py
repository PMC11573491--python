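"""Within-session adjusting-amount delay-discounting (DD) task model.

The task offers a choice between an *immediate* lever dispensing 0-6 sucrose
pellets with no delay and a *delay* lever dispensing a fixed six pellets after
a session-constant delay. The number of pellets on the immediate lever (the
``i-value``) adjusts trial to trial: each delay choice increments it and each
immediate choice decrements it, clamped to [0, 6]. Two consecutive choice
responses on the same lever trigger a *forced* trial on the other lever.
Sessions start at i = 3 and end after a fixed number of choice trials or a
wall-clock limit, whichever comes first.

This module provides the trial/session data model, the task's transition
rules, and a softmax agent simulator used by the synthetic-data generators.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

IMMEDIATE = "immediate"
DELAY = "delay"
LEVERS = (IMMEDIATE, DELAY)

#: Fixed number of pellets on the delay lever.
FIXED_DELAY_AMOUNT = 6
#: i-value on the first trial of every session.
INITIAL_I_VALUE = 3
#: Inclusive bounds of the adjusting immediate amount, in pellets.
I_VALUE_MIN, I_VALUE_MAX = 0, 6
#: Delays (s) used across the experiment.
STANDARD_DELAYS_S = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)


class InvalidStateError(ValueError):
    """Raised when task state violates the task rules (e.g. i-value out of range)."""


def other_lever(lever: str) -> str:
    if lever not in LEVERS:
        raise ValueError(f"unknown lever {lever!r}")
    return DELAY if lever == IMMEDIATE else IMMEDIATE


@dataclass
class TrialRecord:
    """One behavioral trial.

    Timestamps are seconds from session start and strictly increase within a
    trial (house light -> initiation -> choice -> reward). ``choice_latency``
    is the time from lever re-extension to the choice press.
    """

    session_id: str
    trial_index: int
    kind: str  # {"choice", "forced"}
    forced_lever: str  # {"immediate", "delay", "none"}
    chosen_lever: str  # {"immediate", "delay"}
    i_value: int
    delay_s: float
    laser: str = "n/a"  # {"on", "off", "n/a"}
    t_house_light: float = 0.0
    t_initiation: float = 0.0
    t_choice: float = 0.0
    t_reward: float = 0.0
    choice_latency: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("choice", "forced"):
            raise ValueError(f"trial kind must be 'choice' or 'forced', got {self.kind!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index starts at 1")
        if not (I_VALUE_MIN <= self.i_value <= I_VALUE_MAX):
            raise InvalidStateError(f"i_value {self.i_value} outside [0, 6]")
        if self.chosen_lever not in LEVERS:
            raise ValueError(f"unknown chosen_lever {self.chosen_lever!r}")
        if self.kind == "forced":
            if self.forced_lever not in LEVERS:
                raise ValueError("forced trial needs a forced_lever")
            if self.chosen_lever != self.forced_lever:
                raise ValueError("on a forced trial only the forced lever is available")
        elif self.forced_lever != "none":
            raise ValueError("choice trial must have forced_lever='none'")
        ts = (self.t_house_light, self.t_initiation, self.t_choice, self.t_reward)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"timestamps must strictly increase within a trial, got {ts}")


@dataclass
class SessionRecord:
    """An ordered sequence of trials at a single delay."""

    session_id: str
    delay_s: float
    max_choice_trials: int
    max_duration_s: float
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for expected, tr in enumerate(self.trials, start=1):
            if tr.trial_index != expected:
                raise ValueError("trial_index must be contiguous from 1")
        if self.n_choice_trials > self.max_choice_trials:
            raise ValueError("more choice trials than max_choice_trials")

    @property
    def n_choice_trials(self) -> int:
        return sum(tr.kind == "choice" for tr in self.trials)

    def choice_trials(self) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.kind == "choice"]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(tr) for tr in self.trials])
        df.attrs.update(
            session_id=self.session_id,
            delay_s=self.delay_s,
            max_choice_trials=self.max_choice_trials,
            max_duration_s=self.max_duration_s,
        )
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        delay_s: float | None = None,
        max_choice_trials: int | None = None,
        max_duration_s: float | None = None,
    ) -> "SessionRecord":
        attrs = df.attrs
        trials = [
            TrialRecord(
                session_id=str(r.session_id),
                trial_index=int(r.trial_index),
                kind=str(r.kind),
                forced_lever=str(r.forced_lever),
                chosen_lever=str(r.chosen_lever),
                i_value=int(r.i_value),
                delay_s=float(r.delay_s),
                laser=str(r.laser),
                t_house_light=float(r.t_house_light),
                t_initiation=float(r.t_initiation),
                t_choice=float(r.t_choice),
                t_reward=float(r.t_reward),
                choice_latency=float(r.choice_latency),
            )
            for r in df.itertuples()
        ]
        if not trials:
            raise ValueError("empty session table")
        return cls(
            session_id=trials[0].session_id,
            delay_s=float(delay_s if delay_s is not None else attrs.get("delay_s", trials[0].delay_s)),
            max_choice_trials=int(
                max_choice_trials
                if max_choice_trials is not None
                else attrs.get("max_choice_trials", sum(t.kind == "choice" for t in trials))
            ),
            max_duration_s=float(
                max_duration_s
                if max_duration_s is not None
                else attrs.get("max_duration_s", trials[-1].t_reward + 1.0)
            ),
            trials=trials,
        )

    def to_csv(self, path) -> None:
        """One row per trial; columns are the TrialRecord fields."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **session_params) -> "SessionRecord":
        return cls.from_dataframe(pd.read_csv(path), **session_params)

    def to_json(self, path=None) -> str | None:
        payload = {
            "session_id": self.session_id,
            "delay_s": self.delay_s,
            "max_choice_trials": self.max_choice_trials,
            "max_duration_s": self.max_duration_s,
            "trials": [asdict(tr) for tr in self.trials],
        }
        text = json.dumps(payload, indent=1)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source) -> "SessionRecord":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        trials = [TrialRecord(**tr) for tr in payload["trials"]]
        return cls(
            session_id=payload["session_id"],
            delay_s=payload["delay_s"],
            max_choice_trials=payload["max_choice_trials"],
            max_duration_s=payload["max_duration_s"],
            trials=trials,
        )


@dataclass
class AgentPolicy:
    """Softmax agent over hyperbolically discounted subjective values.

    The immediate option is worth the current i-value; the delay option is
    worth ``a / (1 + k_true * d)``. ``temperature`` is the softmax inverse
    noise (beta); ``math.inf`` gives greedy argmax with ties broken toward
    the delay lever, matching the empirical baseline delay-lever bias.
    """

    k_true: float
    a: int = FIXED_DELAY_AMOUNT
    temperature: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.a != FIXED_DELAY_AMOUNT:
            raise ValueError("the delay lever always dispenses six pellets")

    def subjective_values(self, i_value: int, delay_s: float) -> tuple[float, float]:
        """(v_immediate, v_delay) per the hyperbolic discount model."""
        v_imm = float(i_value)
        v_del = self.a / (1.0 + self.k_true * delay_s)
        return v_imm, v_del

    def p_delay(self, i_value: int, delay_s: float) -> float:
        v_imm, v_del = self.subjective_values(i_value, delay_s)
        dv = v_del - v_imm
        if math.isinf(self.temperature):
            return 1.0 if dv >= 0 else 0.0  # tie-break toward delay
        # logistic softmax over the two options
        x = self.temperature * dv
        if x >= 0:
            return 1.0 / (1.0 + math.exp(-x))
        ex = math.exp(x)
        return ex / (1.0 + ex)


def update_i_value(i: int, choice: str) -> int:
    """Apply the adjusting-amount rule: delay choices increment, immediate
    choices decrement the i-value by one pellet, clamped to [0, 6]."""
    if not (I_VALUE_MIN <= i <= I_VALUE_MAX):
        raise InvalidStateError(f"i-value {i} outside [0, 6]")
    if choice == DELAY:
        return min(i + 1, I_VALUE_MAX)
    if choice == IMMEDIATE:
        return max(i - 1, I_VALUE_MIN)
    raise ValueError(f"unknown lever {choice!r}")


def next_trial_kind(history: Sequence[TrialRecord]) -> tuple[str, str | None]:
    """Decide whether the next trial is free choice or forced.

    Two consecutive same-lever *choice* responses, with no forced trial in
    between, force the next trial onto the other lever. A completed forced
    trial resets the consecutive counter. An omitted forced trial simply does
    not enter the history, so the same forced prescription is returned again
    (the forced trial repeats until pressed).

    Returns ``("choice", None)`` or ``("forced", lever)``.
    """
    streak_lever: str | None = None
    streak = 0
    for tr in history:
        if tr.kind == "forced":
            streak_lever, streak = None, 0
        else:
            if tr.chosen_lever == streak_lever:
                streak += 1
            else:
                streak_lever, streak = tr.chosen_lever, 1
    if streak >= 2:
        assert streak_lever is not None
        return "forced", other_lever(streak_lever)
    return "choice", None


# Fixed task timing used by the simulator (seconds).
_HOUSE_LIGHT_S = 10.0
_LEVER_RETRACT_S = 1.0
_REWARD_TO_NEXT_TRIAL_S = 5.0


def _draw_choice_latency(rng: np.random.Generator, dv: float) -> float:
    """Log-normal latency whose median shrinks as the value difference grows.

    Harder (small |dv|) choices are slower: median = 0.5 * (1 + 1/(|dv|+0.5)) s.
    """
    median = 0.5 * (1.0 + 1.0 / (abs(dv) + 0.5))
    return float(rng.lognormal(mean=math.log(median), sigma=0.4))


def simulate_session(
    policy: AgentPolicy,
    delay_s: float,
    max_choice_trials: int = 30,
    max_duration_s: float = 35 * 60.0,
    seed: int | None = None,
    session_id: str = "sim",
    laser: str = "n/a",
) -> SessionRecord:
    """Simulate one adjusting-amount DD session under a softmax agent.

    The session starts at i = 3 and terminates after ``max_choice_trials``
    choice trials or ``max_duration_s`` seconds, whichever comes first.
    Forced trials are inserted by the two-consecutive-same-lever rule and do
    not alter the i-value. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(policy.seed if seed is None else seed)
    trials: list[TrialRecord] = []
    i_value = INITIAL_I_VALUE
    t = 0.0
    n_choice = 0

    while n_choice < max_choice_trials and t < max_duration_s:
        kind, forced = next_trial_kind(trials)
        v_imm, v_del = policy.subjective_values(i_value, delay_s)
        dv = v_del - v_imm
        if kind == "forced":
            chosen = forced
        else:
            chosen = DELAY if rng.random() < policy.p_delay(i_value, delay_s) else IMMEDIATE

        t_house = t
        t_init = t_house + _HOUSE_LIGHT_S + float(rng.exponential(1.5)) + 1e-3
        latency = _draw_choice_latency(rng, dv)
        t_choice = t_init + _LEVER_RETRACT_S + latency
        t_reward = t_choice + (delay_s if chosen == DELAY else 0.0) + 1e-3

        trials.append(
            TrialRecord(
                session_id=session_id,
                trial_index=len(trials) + 1,
                kind=kind,
                forced_lever=forced if kind == "forced" else "none",
                chosen_lever=chosen,
                i_value=i_value,
                delay_s=delay_s,
                laser=laser,
                t_house_light=t_house,
                t_initiation=t_init,
                t_choice=t_choice,
                t_reward=t_reward,
                choice_latency=latency,
            )
        )
        if kind == "choice":
            n_choice += 1
            i_value = update_i_value(i_value, chosen)
        t = t_reward + _REWARD_TO_NEXT_TRIAL_S

    return SessionRecord(
        session_id=session_id,
        delay_s=delay_s,
        max_choice_trials=max_choice_trials,
        max_duration_s=max_duration_s,
        trials=trials,
    )


def pellets_earned(session: SessionRecord, include_forced: bool = False) -> int:
    """Total pellets collected, counting choice trials (optionally forced too)."""
    total = 0
    for tr in session.trials:
        if tr.kind == "forced" and not include_forced:
            continue
        total += FIXED_DELAY_AMOUNT if tr.chosen_lever == DELAY else tr.i_value
    return total
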