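"""Peri-event spike-train processing.

Spike trains (sorted spike times per neuron) are aligned to the choice press,
binned at 200 ms with an inclusive-endpoint convention (a -15..+15 s window
yields 151 bins; -19..+1 s yields 101), smoothed (5-bin moving average by
default, optionally a Gaussian kernel), and z-scored per neuron. Condition
averages with per-timepoint FDR-corrected t tests reproduce the grand-average
firing-rate comparison across lever x i-value conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .stats import fdr_by
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_S = 0.2
#: Peri-choice window for firing-rate comparisons (151 bins at 200 ms).
RATE_WINDOW = (-15.0, 15.0)
#: Peri-choice window for the state-space analysis (101 bins at 200 ms).
STATE_WINDOW = (-19.0, 1.0)


def bin_count(window: tuple[float, float], bin_width: float) -> int:
    """Number of bins under the inclusive-endpoint convention:
    ``round((end - start) / width) + 1``."""
    start, end = window
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if end <= start:
        raise ValueError("window end must exceed start")
    return int(round((end - start) / bin_width)) + 1


@dataclass
class SpikeTable:
    """Sorted spike times per neuron for one session."""

    session_id: str
    spikes: pd.DataFrame  # columns: neuron_id, time_s

    def __post_init__(self) -> None:
        required = {"neuron_id", "time_s"}
        if not required.issubset(self.spikes.columns):
            raise ValueError(f"spike table needs columns {sorted(required)}")
        if (self.spikes["time_s"] < 0).any():
            raise ValueError("spike times must be nonnegative")
        self.spikes = self.spikes.sort_values(["neuron_id", "time_s"], kind="stable").reset_index(
            drop=True
        )

    @property
    def neuron_ids(self) -> list:
        return sorted(self.spikes["neuron_id"].unique().tolist())

    def times_for(self, neuron_id) -> np.ndarray:
        return self.spikes.loc[self.spikes["neuron_id"] == neuron_id, "time_s"].to_numpy()

    def to_csv(self, path) -> None:
        self.spikes.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, session_id: str = "unknown") -> "SpikeTable":
        return cls(session_id=session_id, spikes=pd.read_csv(path))


@dataclass
class AlignedTensor:
    """Peri-event firing rates: neurons x time bins x trials (Hz).

    Bins are centered on offsets ``start, start + w, ..., end`` relative to
    the alignment event; each bin spans ``[center - w/2, center + w/2)``.
    """

    rates: np.ndarray  # (n_neurons, n_bins, n_trials)
    window: tuple[float, float]
    bin_width_s: float
    neuron_ids: list
    event: str = "choice"
    smoothing: str = "none"
    truncated: np.ndarray | None = None  # per-trial flag: window exceeded recording span

    def __post_init__(self) -> None:
        expected = bin_count(self.window, self.bin_width_s)
        if self.rates.ndim != 3 or self.rates.shape[1] != expected:
            raise ValueError(
                f"rates must be (neurons, {expected} bins, trials); got {self.rates.shape}"
            )
        if self.rates.shape[0] != len(self.neuron_ids):
            raise ValueError("neuron_ids must match the first axis of rates")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[2]

    def bin_centers(self) -> np.ndarray:
        """Bin-center offsets (s) relative to the alignment event."""
        return self.window[0] + self.bin_width_s * np.arange(self.n_bins)

    def trial_average(self) -> np.ndarray:
        """Mean rate over trials: (n_neurons, n_bins)."""
        return self.rates.mean(axis=2)


def align_and_bin(
    spikes: SpikeTable,
    event_times,
    window: tuple[float, float] = STATE_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    recording_span: tuple[float, float] | None = None,
) -> AlignedTensor:
    """Align spike trains to events and bin them into firing rates (Hz).

    Trials whose window falls partly outside ``recording_span`` (when given)
    are flagged in ``truncated`` rather than dropped.
    """
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("no alignment events")
    n_bins = bin_count(window, bin_width)
    edges = window[0] - bin_width / 2.0 + bin_width * np.arange(n_bins + 1)
    neuron_ids = spikes.neuron_ids
    rates = np.zeros((len(neuron_ids), n_bins, events.size))
    for ni, nid in enumerate(neuron_ids):
        t = spikes.times_for(nid)
        for ei, ev in enumerate(events):
            counts, _ = np.histogram(t - ev, bins=edges)
            rates[ni, :, ei] = counts / bin_width
    truncated = None
    if recording_span is not None:
        lo, hi = recording_span
        truncated = (events + edges[0] < lo) | (events + edges[-1] > hi)
        if truncated.any():
            logger.info("%d of %d trials have truncated windows", int(truncated.sum()), events.size)
    return AlignedTensor(
        rates=rates,
        window=window,
        bin_width_s=bin_width,
        neuron_ids=neuron_ids,
        truncated=truncated,
    )


def smooth(
    tensor: AlignedTensor,
    method: str = "moving_average",
    ma_bins: int = 5,
    gaussian_sigma_s: float = 0.010,
) -> AlignedTensor:
    """Smooth rates along time, per neuron and trial (reflected edges).

    ``moving_average`` applies a flat kernel of ``ma_bins`` bins (default 5);
    ``gaussian`` convolves with a Gaussian of ``gaussian_sigma_s`` seconds
    (default 10 ms; note that at a 200 ms bin width such a narrow kernel is
    nearly an identity on the binned series).
    """
    if method == "moving_average":
        if ma_bins > tensor.n_bins:
            raise ValueError("moving-average kernel longer than the series")
        smoothed = uniform_filter1d(tensor.rates, size=ma_bins, axis=1, mode="reflect")
        desc = f"moving_average({ma_bins} bins)"
    elif method == "gaussian":
        sigma_bins = gaussian_sigma_s / tensor.bin_width_s
        if 2 * 4 * sigma_bins > 2 * tensor.n_bins:
            raise ValueError("gaussian kernel longer than the series")
        smoothed = gaussian_filter1d(tensor.rates, sigma=sigma_bins, axis=1, mode="reflect")
        desc = f"gaussian(sigma={gaussian_sigma_s * 1e3:g} ms)"
    else:
        raise ValueError("method must be 'moving_average' or 'gaussian'")
    prior = "" if tensor.smoothing == "none" else tensor.smoothing + " -> "
    return replace(tensor, rates=smoothed, smoothing=prior + desc)


class ZScoreNeurons(TransformerMixin, BaseEstimator):
    """Column-wise (per-neuron) z-scoring for (observations x neurons) matrices.

    Zero-variance neurons cannot be standardized and are dropped at
    transform time (indices kept in ``dropped_``). ``ddof`` selects the
    population (0, default) or sample (1) standard deviation.
    """

    def __init__(self, ddof: int = 0):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D (observations x neurons) matrix")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=self.ddof)
        self.keep_ = self.scale_ > 0
        self.dropped_ = np.flatnonzero(~self.keep_)
        if self.dropped_.size:
            logger.info("dropping %d zero-variance neurons", self.dropped_.size)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        Z = (X[:, self.keep_] - self.mean_[self.keep_]) / self.scale_[self.keep_]
        return Z


def zscore_rates(data, ddof: int = 0):
    """Z-score per neuron over the concatenation of all time bins (and trials).

    Accepts an :class:`AlignedTensor` (per-neuron over bins x trials) or a
    2-D (observations x neurons) matrix. Zero-variance neurons are dropped.

    Returns ``(zscored, dropped)`` where ``dropped`` lists the dropped
    neuron ids (tensor input) or column indices (matrix input).
    """
    if isinstance(data, AlignedTensor):
        flat = data.rates.reshape(data.n_neurons, -1)
        sd = flat.std(axis=1, ddof=ddof)
        keep = sd > 0
        dropped = [nid for nid, k in zip(data.neuron_ids, keep) if not k]
        if dropped:
            logger.info("dropping %d zero-variance neurons", len(dropped))
        mean = flat[keep].mean(axis=1, keepdims=True)
        scale = sd[keep, None]
        z = (flat[keep] - mean) / scale
        out = replace(
            data,
            rates=z.reshape(keep.sum(), data.n_bins, data.n_trials),
            neuron_ids=[nid for nid, k in zip(data.neuron_ids, keep) if k],
        )
        return out, dropped
    zs = ZScoreNeurons(ddof=ddof).fit(data)
    return zs.transform(data), zs.dropped_.tolist()


@dataclass
class TimepointTests:
    """Per-bin paired t tests with Benjamini-Yekutieli FDR correction."""

    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray  # p_adjusted < alpha
    alpha: float


@dataclass
class ConditionAverages:
    """Grand-average condition traces with per-timepoint contrasts."""

    means: dict  # condition -> (n_bins,) grand-average rate over neurons
    sems: dict  # condition -> (n_bins,) SEM over neurons
    tests: dict  # (cond_a, cond_b) -> TimepointTests
    bin_centers: np.ndarray


def condition_averages(
    tensor: AlignedTensor,
    trial_labels,
    contrasts=(("IM-low", "IM-high"), ("DEL-low", "DEL-high")),
    alpha: float = 0.05,
) -> ConditionAverages:
    """Grand-average rates per condition and per-bin FDR-corrected t tests.

    ``trial_labels`` assigns each trial of the tensor to a condition (e.g.
    lever x i-value stratum). Per condition, rates are averaged over that
    condition's trials, then the grand average and SEM are taken over
    neurons. For each requested contrast a paired t test across neurons is
    run at every time bin and Benjamini-Yekutieli corrected across bins.
    """
    labels = np.asarray(trial_labels)
    if labels.size != tensor.n_trials:
        raise ValueError("one label per trial required")
    conditions = sorted(set(labels.tolist()))
    per_neuron: dict[str, np.ndarray] = {}
    means, sems = {}, {}
    for cond in conditions:
        mask = labels == cond
        if mask.sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 trials")
        pn = tensor.rates[:, :, mask].mean(axis=2)  # neurons x bins
        per_neuron[cond] = pn
        means[cond] = pn.mean(axis=0)
        sems[cond] = pn.std(axis=0, ddof=1) / np.sqrt(pn.shape[0])
    tests = {}
    for ca, cb in contrasts:
        if ca not in per_neuron or cb not in per_neuron:
            continue
        t, p = sps.ttest_rel(per_neuron[ca], per_neuron[cb], axis=0)
        p = np.nan_to_num(p, nan=1.0)  # identical columns -> undefined t; no evidence
        p_adj = fdr_by(p)
        tests[(ca, cb)] = TimepointTests(
            p_raw=p, p_adjusted=p_adj, significant=p_adj < alpha, alpha=alpha
        )
    return ConditionAverages(
        means=means, sems=sems, tests=tests, bin_centers=tensor.bin_centers()
    )


def retained_neurons(
    spikes: SpikeTable,
    events_by_type: dict,
    window: tuple[float, float] = STATE_WINDOW,
) -> list:
    """Neuron-exclusion rule for the state-space analysis.

    A neuron is retained iff it fires at least one spike inside the analysis
    window of the trials of *every* run trial type present (both the third
    and fourth trials, which enter ``events_by_type`` as separate types).
    """
    start, end = window
    kept = []
    for nid in spikes.neuron_ids:
        t = spikes.times_for(nid)
        ok = True
        for events in events_by_type.values():
            events = np.asarray(events, dtype=float)
            if events.size == 0:
                continue
            fired = any(np.any((t >= ev + start) & (t <= ev + end)) for ev in events)
            if not fired:
                ok = False
                break
        if ok:
            kept.append(nid)
    return kept


def retention_bookkeeping(starting: int, excluded: int) -> int:
    """Neurons entering the state-space analysis after exclusion."""
    if excluded > starting or starting < 0 or excluded < 0:
        raise ValueError("excluded count must lie in [0, starting]")
    return starting - excluded
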