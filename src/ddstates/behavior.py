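"""Discounting and choice-strategy metrics from adjusting-amount DD sessions.

Core quantities:

* **Indifference point** — mean i-value over the last ``n`` choice trials of a
  session; the amount at which the immediate and delayed options are valued
  equally.
* **Hyperbolic discount rate k** — least-squares fit of the Mazur model
  ``v(d) = a / (1 + k d)`` to indifference points across delays, exposed as an
  sklearn-style regressor (:class:`MazurDiscounting`).
* **AUC** — normalized area under the indifference-point curve, a
  model-free discounting index.
* **Extra-sum-of-squares F test** — whether one hyperbolic curve describes
  two conditions or each needs its own k.
* **Consecutive-choice run lengths** per choice type (lever x low/high
  i-value) with gamma fits, and rank-transformed choice-latency contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .task import DELAY, FIXED_DELAY_AMOUNT, SessionRecord, TrialRecord

CHOICE_TYPES = ("IM-low", "IM-high", "DEL-low", "DEL-high")

#: i-value < 4 is "low", i-value > 3 is "high" (exhaustive over 0..6).
LOW_HIGH_SPLIT = 4


def indifference_point(session: SessionRecord, n_last: int = 10) -> float:
    """Mean i-value over the last ``n_last`` choice trials (forced excluded)."""
    choices = session.choice_trials()
    if len(choices) < n_last:
        raise ValueError(
            f"session has {len(choices)} choice trials; {n_last} required for an indifference point"
        )
    return float(np.mean([tr.i_value for tr in choices[-n_last:]]))


def magnitude_discrimination_threshold(fraction: float, a: int = FIXED_DELAY_AMOUNT) -> float:
    """Inclusion criterion at the 0 s delay: ``fraction`` of the maximum reward.

    E.g. 80% of six pellets = 4.8 and 70% = 4.2 pellets.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return fraction * a


def hyperbolic_value(d, k, a: float = FIXED_DELAY_AMOUNT):
    """Mazur hyperbolic subjective value v = a / (1 + k d)."""
    return a / (1.0 + k * np.asarray(d, dtype=float))


class MazurDiscounting(RegressorMixin, BaseEstimator):
    """Least-squares fit of the hyperbolic discount model v = a / (1 + k d).

    The single free parameter is the discount rate ``k`` (1/s), constrained
    nonnegative and found by a deterministic bounded 1-D minimization of the
    sum of squared errors between predicted values and observed indifference
    points.

    Parameters
    ----------
    a : float
        Fixed amount of the delayed reward, in pellets.
    k_max : float
        Upper bound of the search interval for k.

    Attributes
    ----------
    k_ : float
        Fitted discount rate (1/s).
    sse_ : float
        Residual sum of squares at ``k_``.
    """

    def __init__(self, a: float = FIXED_DELAY_AMOUNT, k_max: float = 100.0):
        self.a = a
        self.k_max = k_max

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).reshape(-1)
        ip = np.asarray(y, dtype=float).reshape(-1)
        if d.shape != ip.shape:
            raise ValueError("delays and indifference points must have equal length")
        if np.unique(d).size < 2:
            raise ValueError("need at least two distinct delays to fit k")
        if np.any(ip < 0) or np.any(ip > self.a):
            raise ValueError(f"indifference points must lie in [0, {self.a}]")

        def sse(k: float) -> float:
            r = ip - hyperbolic_value(d, k, self.a)
            return float(r @ r)

        res = optimize.minimize_scalar(
            sse, bounds=(0.0, self.k_max), method="bounded",
            options={"xatol": 1e-10},
        )
        # the bounded minimizer never lands exactly on the boundary; snap if flat there
        k = float(res.x)
        if sse(0.0) <= res.fun + 1e-12:
            k = 0.0
        self.k_ = k
        self.sse_ = sse(k)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "k_")
        return hyperbolic_value(np.asarray(X, dtype=float).reshape(-1), self.k_, self.a)


@dataclass
class DiscountingCurve:
    """Indifference points across delays with the fitted hyperbolic model."""

    delays: np.ndarray
    indifference_points: np.ndarray
    a: float = FIXED_DELAY_AMOUNT
    k: float = float("nan")
    sse: float = float("nan")

    @classmethod
    def fit(cls, delays, indifference_points, a: float = FIXED_DELAY_AMOUNT) -> "DiscountingCurve":
        est = MazurDiscounting(a=a).fit(delays, indifference_points)
        return cls(
            delays=np.asarray(delays, dtype=float),
            indifference_points=np.asarray(indifference_points, dtype=float),
            a=a,
            k=est.k_,
            sse=est.sse_,
        )


def fit_mazur(delays, indifference_points, a: float = FIXED_DELAY_AMOUNT) -> tuple[float, float]:
    """Fit the hyperbolic model; returns ``(k, sse)``."""
    est = MazurDiscounting(a=a).fit(delays, indifference_points)
    return est.k_, est.sse_


def auc_discounting(delays, indifference_points, a: float = FIXED_DELAY_AMOUNT) -> float:
    """Normalized area under the discounting curve (Myerson-Green style).

    Trapezoidal area under indifference points versus delay, divided by the
    delay span times the delayed amount, so a flat curve at ``a`` gives 1 and
    complete discounting gives 0.
    """
    d = np.asarray(delays, dtype=float)
    ip = np.asarray(indifference_points, dtype=float)
    if d.size < 2:
        raise ValueError("AUC needs at least two delays")
    order = np.argsort(d)
    d, ip = d[order], ip[order]
    span = d[-1] - d[0]
    if span <= 0:
        raise ValueError("delays must span a positive range")
    return float(np.trapezoid(ip, d) / (span * a))


@dataclass
class CurveComparison:
    """Extra-sum-of-squares F test between two discounting conditions."""

    F: float
    df_num: int
    df_den: int
    p: float
    k_pooled: float
    k_a: float
    k_b: float
    sse_pooled: float
    sse_separate: float
    degenerate: bool = False  # SSE_separate == 0; F reported as inf


def compare_curves_ess_f(
    delays_a, ips_a, delays_b, ips_b, a: float = FIXED_DELAY_AMOUNT
) -> CurveComparison:
    """Test whether one hyperbolic curve fits both conditions.

    Fits a shared-k model to the pooled points and separate k's per
    condition, then
    ``F = ((SSE_p - SSE_s) / (df_p - df_s)) / (SSE_s / df_s)``
    with df = n - (number of fitted parameters).
    """
    da, ia = np.asarray(delays_a, float), np.asarray(ips_a, float)
    db, ib = np.asarray(delays_b, float), np.asarray(ips_b, float)
    ka, sse_a = fit_mazur(da, ia, a)
    kb, sse_b = fit_mazur(db, ib, a)
    d_pool = np.concatenate([da, db])
    ip_pool = np.concatenate([ia, ib])
    kp, sse_p = fit_mazur(d_pool, ip_pool, a)

    sse_s = sse_a + sse_b
    n = d_pool.size
    df_s = n - 2
    df_p = n - 1
    df_num = df_p - df_s
    if df_s <= 0:
        raise ValueError("too few points for the extra-sum-of-squares test")
    if sse_s <= 1e-14:
        if sse_p <= 1e-12:  # both models fit perfectly: no evidence of difference
            return CurveComparison(
                F=0.0, df_num=df_num, df_den=df_s, p=1.0,
                k_pooled=kp, k_a=ka, k_b=kb,
                sse_pooled=sse_p, sse_separate=sse_s,
            )
        return CurveComparison(
            F=float("inf"), df_num=df_num, df_den=df_s, p=0.0,
            k_pooled=kp, k_a=ka, k_b=kb,
            sse_pooled=sse_p, sse_separate=sse_s, degenerate=True,
        )
    F = ((sse_p - sse_s) / df_num) / (sse_s / df_s)
    F = max(F, 0.0)  # guard tiny negative from optimizer tolerance
    p = float(stats.f.sf(F, df_num, df_s))
    return CurveComparison(
        F=float(F), df_num=df_num, df_den=df_s, p=p,
        k_pooled=kp, k_a=ka, k_b=kb,
        sse_pooled=sse_p, sse_separate=sse_s,
    )


def classify_choice_type(trial: TrialRecord) -> str:
    """Label a choice trial by lever and i-value stratum (low < 4 <= high)."""
    if trial.kind != "choice":
        raise ValueError("only choice trials have a choice type")
    lever = "DEL" if trial.chosen_lever == DELAY else "IM"
    stratum = "low" if trial.i_value < LOW_HIGH_SPLIT else "high"
    return f"{lever}-{stratum}"


@dataclass
class ChoiceTypeRuns:
    """Maximal consecutive-choice run lengths of one choice type with a gamma fit."""

    choice_type: str
    run_lengths: list[int]
    gamma_shape: float = float("nan")
    gamma_scale: float = float("nan")

    @property
    def n_trials(self) -> int:
        return int(sum(self.run_lengths))

    def empirical_pdf(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, probability mass) over the observed run lengths."""
        lengths, counts = np.unique(np.asarray(self.run_lengths), return_counts=True)
        return lengths, counts / counts.sum()


def _run_lengths_by_type(sessions: list[SessionRecord]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {t: [] for t in CHOICE_TYPES}
    for session in sessions:
        labels = [classify_choice_type(tr) for tr in session.choice_trials()]
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            out[labels[i]].append(j - i)
            i = j
    return out


def consecutive_choice_pdf(sessions, choice_type: str) -> ChoiceTypeRuns:
    """Run-length distribution of consecutive same-type choices.

    Choice trials are labeled by lever x i-value stratum; maximal consecutive
    runs of ``choice_type`` are collected over choice trials only (runs of
    length 1 included) and a gamma distribution is fitted by maximum
    likelihood (method-of-moments start, location fixed at 0). With fewer
    than two runs the fit is skipped with a warning.
    """
    if choice_type not in CHOICE_TYPES:
        raise ValueError(f"choice_type must be one of {CHOICE_TYPES}")
    if isinstance(sessions, SessionRecord):
        sessions = [sessions]
    lengths = _run_lengths_by_type(list(sessions))[choice_type]
    result = ChoiceTypeRuns(choice_type=choice_type, run_lengths=lengths)
    if len(lengths) < 2:
        warnings.warn(f"fewer than 2 runs of type {choice_type}; gamma fit skipped")
        return result
    x = np.asarray(lengths, dtype=float)
    if np.ptp(x) == 0:  # degenerate: all runs equal; MLE shape diverges
        warnings.warn(f"all runs of type {choice_type} equal; gamma fit skipped")
        return result
    # method-of-moments start: shape = mean^2/var, scale = var/mean
    m, v = x.mean(), x.var()
    shape0 = m * m / v
    shape, _, scale = stats.gamma.fit(x, shape0, floc=0, scale=v / m)
    result.gamma_shape = float(shape)
    result.gamma_scale = float(scale)
    return result


def all_choice_type_runs(sessions) -> dict[str, ChoiceTypeRuns]:
    """``consecutive_choice_pdf`` for each of the four choice types."""
    return {t: consecutive_choice_pdf(sessions, t) for t in CHOICE_TYPES}


@dataclass
class LatencyRankContrast:
    """Rank-transformed paired latency comparison between run trials 3 and 4."""

    mean_rank_3: float
    mean_rank_4: float
    statistic: float
    z: float
    p: float
    n: int


def latency_rank_contrast(trial3_latencies, trial4_latencies) -> LatencyRankContrast:
    """Compare paired choice latencies after rank transformation.

    Latencies from both trials are pooled and rank-transformed (limiting the
    positive skew of reaction times); mean ranks per trial are reported and a
    Wilcoxon signed-rank test is run on the pairs. All-zero differences give
    statistic 0, p = 1.
    """
    x3 = np.asarray(trial3_latencies, dtype=float)
    x4 = np.asarray(trial4_latencies, dtype=float)
    if x3.shape != x4.shape:
        raise ValueError("latency vectors must be paired (equal length)")
    n = x3.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    ranks = stats.rankdata(np.concatenate([x3, x4]))
    r3, r4 = ranks[:n], ranks[n:]
    diffs = x4 - x3
    if np.allclose(diffs, 0.0):
        return LatencyRankContrast(float(r3.mean()), float(r4.mean()), 0.0, 0.0, 1.0, n)
    res = stats.wilcoxon(x3, x4, zero_method="wilcox", correction=False, method="approx")
    # signed z from the normal approximation, direction = median shift of trial 4
    z = float(stats.norm.isf(res.pvalue / 2.0)) * (1.0 if np.median(diffs) > 0 else -1.0)
    return LatencyRankContrast(
        mean_rank_3=float(r3.mean()),
        mean_rank_4=float(r4.mean()),
        statistic=float(res.statistic),
        z=z,
        p=float(res.pvalue),
        n=n,
    )
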