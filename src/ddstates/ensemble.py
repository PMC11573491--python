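"""Population state-space trajectories over run trial types and the
trajectory-distance analysis between a run's third and fourth trials.

For each of the eight run trial types (lever x Change/Fail-to-Change x
trial 3/4) a time-bin x neuron firing-rate matrix is built over the 101-bin
peri-choice window. The eight matrices are concatenated (808 rows), columns
are z-scored, and PCA extracts the top three components; each trial type's
rows form a trajectory through that space. The per-bin Euclidean distance
between the third- and fourth-trial trajectories of a run type — the
diagonal of their full pairwise distance matrix — quantifies how much the
population pattern is updated on the fourth trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from . import runs as runs_mod
from .spikes import (
    DEFAULT_BIN_WIDTH_S,
    STATE_WINDOW,
    AlignedTensor,
    SpikeTable,
    ZScoreNeurons,
    align_and_bin,
    bin_count,
    retained_neurons,
    smooth,
)
from .task import SessionRecord

#: Fixed concatenation order of the eight trial types.
TRIAL_TYPE_ORDER = runs_mod.TRIAL_TYPES
RUN_TYPES = ("IM-Change", "IM-FtC", "DEL-Change", "DEL-FtC")


class RunStateSpace(TransformerMixin, BaseEstimator):
    """Z-score + PCA state space over a concatenated time-bin x neuron matrix.

    Fits a full-spectrum PCA on the per-neuron z-scored matrix so the
    complete explained-variance distribution is available; ``transform``
    returns scores for the top ``n_components``. The sign of each component
    is fixed by forcing its largest-magnitude neuron loading positive.

    Attributes
    ----------
    components_ : (n_components_kept, n_neurons_kept) loadings.
    explained_variance_ratio_ : full per-component variance fractions.
    zscorer_ : fitted :class:`ZScoreNeurons` (zero-variance neurons dropped).
    """

    def __init__(self, n_components: int | None = 3, ddof: int = 0):
        self.n_components = n_components
        self.ddof = ddof

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.zscorer_ = ZScoreNeurons(ddof=self.ddof).fit(X)
        Z = self.zscorer_.transform(X)
        if Z.shape[1] < 3:
            raise ValueError("state space needs at least three neurons with variance")
        self.pca_ = PCA(n_components=None, svd_solver="full").fit(Z)
        # deterministic sign: largest-|loading| entry of each component positive
        flip = np.sign(
            self.pca_.components_[
                np.arange(self.pca_.components_.shape[0]),
                np.argmax(np.abs(self.pca_.components_), axis=1),
            ]
        )
        flip[flip == 0] = 1.0
        self.sign_ = flip
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        k = self.pca_.components_.shape[0] if self.n_components is None else self.n_components
        self.n_components_ = int(k)
        self.components_ = (self.pca_.components_ * flip[:, None])[:k]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "pca_")
        Z = self.zscorer_.transform(np.asarray(X, dtype=float))
        scores = self.pca_.transform(Z) * self.sign_[None, :]
        return scores[:, : self.n_components_]


@dataclass
class TrajectorySet:
    """Per-trial-type state-space trajectories with the fitted space."""

    coords: dict  # trial type -> (n_bins, n_components) scores
    explained_variance: np.ndarray  # full per-component fractions
    loadings: np.ndarray  # (n_components, n_neurons_kept)
    scope: str = "global"  # {"global", "per_session"}
    n_bins: int = 0

    @property
    def top_explained_variance(self) -> float:
        k = self.loadings.shape[0]
        return float(self.explained_variance[:k].sum())


def build_state_space(
    trial_type_matrices: dict,
    n_components: int = 3,
    scope: str = "global",
) -> TrajectorySet:
    """Concatenate trial-type matrices, z-score, run PCA, return trajectories.

    ``trial_type_matrices`` maps trial-type labels to (n_bins x n_neurons)
    trial-averaged firing-rate matrices sharing the (post-exclusion) neuron
    set. With the standard eight types of 101 bins each, the concatenated
    matrix is 808 x N.
    """
    labels = [t for t in TRIAL_TYPE_ORDER if t in trial_type_matrices]
    labels += [t for t in trial_type_matrices if t not in labels]
    mats = [np.asarray(trial_type_matrices[t], dtype=float) for t in labels]
    n_bins = mats[0].shape[0]
    n_neurons = mats[0].shape[1]
    for lab, m in zip(labels, mats):
        if m.shape != (n_bins, n_neurons):
            raise ValueError(f"matrix for {lab} has shape {m.shape}, expected {(n_bins, n_neurons)}")
    concat = np.vstack(mats)
    space = RunStateSpace(n_components=n_components).fit(concat)
    scores = space.transform(concat)
    coords = {
        lab: scores[i * n_bins : (i + 1) * n_bins] for i, lab in enumerate(labels)
    }
    return TrajectorySet(
        coords=coords,
        explained_variance=space.explained_variance_ratio_,
        loadings=space.components_,
        scope=scope,
        n_bins=n_bins,
    )


@dataclass
class DistanceSeries:
    """Per-bin Euclidean distance between two trajectories of one run type."""

    values: np.ndarray
    run_type: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be nonnegative")

    @property
    def mean_distance(self) -> float:
        return float(self.values.mean())


def trajectory_distance(traj3, traj4, run_type: str = "") -> DistanceSeries:
    """Per-bin Euclidean distance between third- and fourth-trial trajectories.

    Equals the diagonal of the full pairwise distance matrix between the two
    trajectories' time points.
    """
    a = np.asarray(traj3, dtype=float)
    b = np.asarray(traj4, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trajectory shapes differ: {a.shape} vs {b.shape}")
    return DistanceSeries(values=np.linalg.norm(a - b, axis=1), run_type=run_type)


def trial_type_matrices(
    spikes: SpikeTable,
    session: SessionRecord,
    session_runs: list | None = None,
    window: tuple[float, float] = STATE_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    smoothing: str = "moving_average",
    apply_exclusion: bool = True,
) -> dict:
    """Trial-averaged (n_bins x n_neurons) matrices for the run trial types
    present in a session.

    Spike trains are aligned to the choice press of each run's third and
    fourth trials, binned, smoothed, averaged over that type's trials, and
    restricted to neurons passing the firing-in-every-type exclusion rule.
    """
    if session_runs is None:
        session_runs = runs_mod.segment_runs(session)
    choice_time = {tr.trial_index: tr.t_choice for tr in session.trials}
    events_by_type: dict[str, list[float]] = {}
    for run in session_runs:
        for which, trial_id in ((3, run.trial3_id), (4, run.trial4_id)):
            label = runs_mod.trial_type_label(run, which)
            events_by_type.setdefault(label, []).append(choice_time[trial_id])

    if apply_exclusion:
        keep = set(retained_neurons(spikes, events_by_type, window))
        table = SpikeTable(
            session_id=spikes.session_id,
            spikes=spikes.spikes[spikes.spikes["neuron_id"].isin(keep)].copy(),
        )
    else:
        table = spikes
    if not table.neuron_ids:
        raise ValueError("no neurons survive the exclusion rule")

    matrices = {}
    for label, events in events_by_type.items():
        tensor = align_and_bin(table, events, window=window, bin_width=bin_width)
        if smoothing != "none":
            tensor = smooth(tensor, method=smoothing)
        matrices[label] = tensor.trial_average().T  # bins x neurons
    return matrices


def per_session_distances(
    spikes: SpikeTable,
    session: SessionRecord,
    session_runs: list | None = None,
    window: tuple[float, float] = STATE_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    n_components: int = 3,
) -> dict:
    """Session-level state space and T3-T4 distance series per run type.

    Builds the same concatenate/z-score/PCA recipe from this session's own
    trial-type matrices and returns ``{run_type: DistanceSeries}`` for every
    run type whose third and fourth trials are both present; missing run
    types are simply absent from the result.
    """
    if session_runs is None:
        session_runs = runs_mod.segment_runs(session)
    matrices = trial_type_matrices(spikes, session, session_runs, window, bin_width)
    traj = build_state_space(matrices, n_components=n_components, scope="per_session")
    out = {}
    for rt in RUN_TYPES:
        t3, t4 = f"{rt}-T3", f"{rt}-T4"
        if t3 in traj.coords and t4 in traj.coords:
            out[rt] = trajectory_distance(traj.coords[t3], traj.coords[t4], run_type=rt)
    return out


def distance_tidy_table(per_session: dict) -> pd.DataFrame:
    """Long-format table of distances for the group-level contrasts.

    ``per_session`` maps ``(session_id, delay_s)`` (or just session_id) to a
    ``{run_type: DistanceSeries}`` dict; rows are one (session, run type,
    time bin) observation, ready for the time x run (x delay)
    repeated-measures ANOVA.
    """
    rows = []
    for key, dists in per_session.items():
        if isinstance(key, tuple):
            session_id, delay_s = key
        else:
            session_id, delay_s = key, np.nan
        for rt, series in dists.items():
            for b, v in enumerate(series.values):
                rows.append(
                    {
                        "session_id": session_id,
                        "delay_s": delay_s,
                        "run_type": rt,
                        "time_bin": b,
                        "distance": v,
                    }
                )
    return pd.DataFrame(rows)
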