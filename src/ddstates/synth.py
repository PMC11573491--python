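"""Synthetic behavioral and neural data with known ground truth.

Every pipeline stage can be exercised without animal data: a softmax agent
playing the adjusting-amount task generates behavioral sessions across the
standard delays, and an inhomogeneous-Poisson ensemble generates spike
tables aligned to the choice events of run trials. Two pre-choice rate
templates emulate the two encoding regimes: ``stable`` (constant
condition-dependent modulation throughout the analysis window, as at the
4 s delay) and ``ramping`` (modulation rising linearly over the final
seconds before the choice, as at the 8 s delay). On Change runs the
fourth trial adds a rate offset ``effect_size_hz`` to a fixed random neuron
subset — the planted population-pattern update the distance analysis must
recover. At ``effect_size_hz = 0`` Change and Fail-to-Change trials are
statistically identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import runs as runs_mod
from .spikes import SpikeTable, STATE_WINDOW
from .task import (
    DELAY,
    IMMEDIATE,
    INITIAL_I_VALUE,
    STANDARD_DELAYS_S,
    AgentPolicy,
    SessionRecord,
    TrialRecord,
    next_trial_kind,
    simulate_session,
    update_i_value,
)


@dataclass
class SynthSpec:
    """Parameters of the synthetic experiment.

    Behavioral defaults follow the task protocol (30 choice trials / 35 min
    sessions, delays 0-16 s; the 4/8 s ephys variant uses 40 trials /
    45 min). Neural defaults are desk-scale: 60 neurons at a 5 Hz mean
    baseline with lever-specific modulation of 2 Hz and a Change-trial
    offset of 3 Hz delivered to half the population.
    """

    # behavior
    k_true: float = 0.25
    temperature: float = 1.0
    delays_s: tuple = STANDARD_DELAYS_S
    n_sessions_per_delay: int = 3
    max_choice_trials: int = 30
    max_duration_s: float = 35 * 60.0
    # neural
    n_neurons: int = 60
    baseline_rate_hz: float = 5.0
    template: str = "stable"  # {"stable", "ramping"}
    lever_gain_hz: float = 2.0
    effect_size_hz: float = 3.0  # delta: Change-trial-4 rate offset
    change_fraction: float = 0.5  # fraction of neurons receiving delta
    ramp_duration_s: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template not in ("stable", "ramping"):
            raise ValueError("template must be 'stable' or 'ramping'")
        if self.baseline_rate_hz < 0 or self.effect_size_hz < 0:
            raise ValueError("rates and effect sizes must be nonnegative")

    def policy(self, seed: int | None = None) -> AgentPolicy:
        return AgentPolicy(
            k_true=self.k_true,
            temperature=self.temperature,
            seed=self.seed if seed is None else seed,
        )

    def to_json(self, path) -> None:
        """Serialize alongside generated outputs for provenance."""
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SynthSpec":
        with open(path) as fh:
            payload = json.load(fh)
        payload["delays_s"] = tuple(payload["delays_s"])
        return cls(**payload)


def generate_behavior(spec: SynthSpec) -> dict:
    """Simulated sessions per delay: ``{delay_s: [SessionRecord, ...]}``.

    Session seeds are spawned deterministically from ``spec.seed``; for
    ``k_true > 0`` indifference points decrease with delay.
    """
    ss = np.random.SeedSequence(spec.seed)
    out: dict[float, list[SessionRecord]] = {}
    children = ss.spawn(len(spec.delays_s))
    for child, d in zip(children, spec.delays_s):
        seeds = child.generate_state(spec.n_sessions_per_delay) % (2**31 - 1)
        out[d] = [
            simulate_session(
                spec.policy(),
                delay_s=d,
                max_choice_trials=spec.max_choice_trials,
                max_duration_s=spec.max_duration_s,
                seed=int(s),
                session_id=f"synth-d{d:g}-s{i}",
            )
            for i, s in enumerate(seeds)
        ]
    return out


# Deterministic task timing for scripted sessions (seconds).
_TRIAL_SPACING_S = 30.0


def session_from_choice_sequence(
    choice_levers,
    delay_s: float,
    session_id: str = "scripted",
    seed: int = 0,
    trial_spacing_s: float = _TRIAL_SPACING_S,
) -> SessionRecord:
    """Build a valid session realizing a prescribed choice-lever sequence.

    Forced trials are inserted wherever the task rules require them, the
    i-value dynamics are applied, and trials are spaced ``trial_spacing_s``
    apart so that peri-choice analysis windows do not overlap. Used to
    guarantee coverage of all run trial types in ground-truth tests.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    i_value = INITIAL_I_VALUE
    remaining = list(choice_levers)
    t = 0.0
    while remaining:
        kind, forced = next_trial_kind(trials)
        chosen = forced if kind == "forced" else remaining.pop(0)
        latency = float(rng.uniform(0.4, 1.2))
        t_house = t
        t_init = t_house + 10.0 + 0.5
        t_choice = t_init + 1.0 + latency
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
                t_house_light=t_house,
                t_initiation=t_init,
                t_choice=t_choice,
                t_reward=t_reward,
                choice_latency=latency,
            )
        )
        if kind == "choice":
            i_value = update_i_value(i_value, chosen)
        t += trial_spacing_s
    n_choice = sum(tr.kind == "choice" for tr in trials)
    return SessionRecord(
        session_id=session_id,
        delay_s=delay_s,
        max_choice_trials=n_choice,
        max_duration_s=t + trial_spacing_s,
        trials=trials,
    )


#: A 17-choice block containing one run of each of the four run types
#: (DEL-Change, IM-FtC, DEL-FtC, IM-Change); the trailing single immediate
#: choice keeps repeated blocks from merging streaks across the boundary.
RUN_COVERAGE_BLOCK = (
    [DELAY] * 3 + [IMMEDIATE] * 4 + [DELAY] * 4 + [IMMEDIATE] * 3 + [DELAY] + [IMMEDIATE]
)


def run_coverage_session(
    n_blocks: int = 2, delay_s: float = 8.0, seed: int = 0, session_id: str = "coverage"
) -> SessionRecord:
    """Scripted session whose choice sequence yields ``n_blocks`` runs of
    each of the four run types."""
    return session_from_choice_sequence(
        RUN_COVERAGE_BLOCK * n_blocks, delay_s=delay_s, seed=seed, session_id=session_id
    )


def _template_modulation(tau: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Time course of condition modulation over window offsets ``tau`` (s)."""
    if spec.template == "stable":
        return np.ones_like(tau)
    return np.clip((tau + spec.ramp_duration_s) / spec.ramp_duration_s, 0.0, 1.0)


def generate_spikes(
    spec: SynthSpec,
    session: SessionRecord,
    session_runs: list | None = None,
    window: tuple[float, float] = STATE_WINDOW,
    dt: float = 0.01,
) -> SpikeTable:
    """Inhomogeneous-Poisson spike table aligned to a session's run trials.

    Each neuron fires at a gamma-distributed baseline plus, inside the
    peri-choice window of every run trial, a lever-specific gain times the
    template time course. The lever pattern follows the *run's* lever for
    both the third and fourth trials, so with ``effect_size_hz = 0`` the two
    trials are statistically identical; on Change runs the fourth trial adds
    the ``effect_size_hz`` offset to a fixed random subset of neurons.
    Reproducible for a fixed ``spec.seed``.
    """
    if session_runs is None:
        session_runs = runs_mod.segment_runs(session)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    # heterogeneous baselines with the requested mean
    baselines = rng.gamma(shape=4.0, scale=spec.baseline_rate_hz / 4.0, size=n)
    gains = {
        "IM": rng.uniform(0.0, 2.0 * spec.lever_gain_hz, size=n),
        "DEL": rng.uniform(0.0, 2.0 * spec.lever_gain_hz, size=n),
    }
    n_mod = max(1, int(round(spec.change_fraction * n)))
    change_subset = np.zeros(n)
    change_subset[rng.choice(n, size=n_mod, replace=False)] = 1.0

    t_end = session.trials[-1].t_reward + window[1] + 1.0
    grid = np.arange(0.0, t_end, dt)
    modulation = np.zeros((n, grid.size))
    choice_time = {tr.trial_index: tr.t_choice for tr in session.trials}
    for run in session_runs:
        for which, trial_id in ((3, run.trial3_id), (4, run.trial4_id)):
            tc = choice_time[trial_id]
            lo = np.searchsorted(grid, tc + window[0])
            hi = np.searchsorted(grid, tc + window[1])
            tau = grid[lo:hi] - tc
            m = _template_modulation(tau, spec)
            pattern = gains[run.lever].copy()
            if which == 4 and run.outcome == runs_mod.CHANGE:
                pattern = pattern + spec.effect_size_hz * change_subset
            modulation[:, lo:hi] += pattern[:, None] * m[None, :]

    rows_nid, rows_t = [], []
    for i in range(n):
        lam = (baselines[i] + modulation[i]) * dt
        counts = rng.poisson(lam)
        idx = np.nonzero(counts)[0]
        times = np.repeat(grid[idx], counts[idx]) + rng.uniform(
            0.0, dt, size=int(counts[idx].sum())
        )
        rows_nid.append(np.full(times.size, i))
        rows_t.append(np.sort(times))
    df = pd.DataFrame(
        {
            "neuron_id": np.concatenate(rows_nid).astype(int),
            "time_s": np.concatenate(rows_t),
        }
    )
    return SpikeTable(session_id=session.session_id, spikes=df)
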