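# Methods

## Task model

The simulator implements the within-session adjusting-amount DD procedure:
the delay lever always pays `a = 6` pellets after the session's delay; the
immediate lever pays the current i-value at once. The i-value starts at 3,
increments after each delay choice and decrements after each immediate
choice, clamped to [0, 6]. Two consecutive same-lever *choice* responses
force the next trial onto the other lever; a completed forced trial resets
the consecutive counter, and an omitted forced trial is simply re-issued
(the state machine is a pure function of the completed-trial history).
Sessions terminate after `max_choice_trials` choice trials (30; 40 in the
4/8 s recording variant) or `max_duration_s` (35 min; 45 min), whichever
comes first.

Two modeling decisions were genuinely open and are fixed as follows:

* **Forced trials do not update the i-value.** The task description reports
  no effect of forced trials on i-value; we read that as mechanical
  independence. The alternative (forced outcomes also adjust the amount)
  would couple the titration to the forcing rule and is not supported by the
  published session traces.
* **Forced trials reset the consecutive-same-lever counter**, since a forced
  press on the other lever breaks the pair that triggers forcing. Without
  this reset a session could enter a forced-trial loop.

The synthetic agent chooses by a logistic softmax over hyperbolically
discounted subjective values, `v_imm = i` and `v_del = a/(1 + k_true·d)`,
with inverse-noise `temperature` (default 1–2; `inf` gives greedy argmax
with ties broken toward the delay lever, matching the empirical baseline
delay-lever bias). Choice latencies are log-normal (σ = 0.4) with median
`0.5·(1 + 1/(|Δv| + 0.5))` s, so close-value (hard) choices are slower — the
feature the rank-latency contrasts need.

## Discounting metrics

* **Indifference point**: mean i-value over the last 10 choice trials of a
  session (forced trials excluded). The titration has reached a stationary
  band by then for any reasonable policy.
* **Hyperbolic fit**: `k` minimizes the sum of squared errors between
  `a/(1+kd)` and the indifference points, by a deterministic bounded Brent
  search on k ∈ [0, 100] (`xatol = 1e-10`), with an explicit snap to k = 0
  when the boundary is optimal. The nonnegativity constraint reflects the
  model: negative k would make delayed rewards gain value with delay.
* **AUC**: trapezoidal area under indifference points versus delay,
  normalized by (delay span × a) in the Myerson–Green manner, so 1 means no
  discounting and 0 complete discounting.
* **Extra-sum-of-squares F**: pooled (shared-k) versus separate fits;
  `F = ((SSE_p − SSE_s)/(df_p − df_s)) / (SSE_s/df_s)` with df = n − number
  of fitted parameters. When the separate fits are exact (SSE_s = 0) the
  statistic is reported as infinite with a `degenerate` flag, except when
  the pooled fit is also exact, which returns F = 0, p = 1. Monte-Carlo
  calibration under a shared-k null with Gaussian errors at interior delays
  (1–16 s, σ = 0.15) gives a type-I rate within sampling error of the
  nominal 5%; at d = 0 the curve sits on the 6-pellet measurement ceiling,
  truncating the error distribution and mildly inflating the test, so the
  calibration check deliberately uses interior delays.
* **Consecutive-choice runs**: choice trials are typed by lever × i-value
  stratum (low < 4 ≤ high, exhaustive over 0–6); maximal same-type run
  lengths (length-1 runs included) form the empirical PDF, with a gamma
  distribution fitted by maximum likelihood (location fixed at 0,
  method-of-moments start). Fewer than two runs, or all-equal runs (where
  the MLE diverges), skip the fit with a warning.
* **Latency contrasts**: paired third- versus fourth-trial choice latencies
  are rank-transformed over the pooled pair set (limiting log-normal skew)
  for display, and tested with the Wilcoxon signed-rank test; all-zero
  differences return statistic 0, p = 1 by contract.

## Run segmentation

Runs are three or more consecutive same-lever choice trials; forced trials
are invisible to run continuity. The fourth *choice* trial after the run's
start classifies it (Change / Fail-to-Change); a run reaching the end of the
session unclassified is excluded with a log entry. Within a maximal
same-lever streak of length L ≥ 3 exactly one run is emitted, anchored at
the streak's first three choices (**maximal-anchored** convention). The
published definition does not state how streaks longer than four are
windowed; anchored is the most conservative reading, and a `sliding` mode
(every 3-choice window) is provided for sensitivity analysis. An exhaustive
oracle over all lever sequences of length ≤ 12 pins the semantics.

## Spike processing

Binning uses an inclusive-endpoint convention: bins are centered on offsets
`start, start + w, …, end` relative to the choice press, each spanning
`[c − w/2, c + w/2)`, giving `round((end−start)/w) + 1` bins — 151 for the
−15…+15 s rate window and 101 for the −19…+1 s state-space window at
w = 200 ms. Counts are converted to rates (Hz). Smoothing defaults to a
5-bin moving average along time with reflected edges; a Gaussian kernel
(σ = 10 ms) is also available, though at a 200 ms bin width it is nearly an
identity and is retained mainly for completeness of the processing options.
Binning and smoothing are linear in the spike trains, which the tests verify
directly.

Z-scoring is per neuron over the concatenation axis (all bins × trials, or
all rows of the concatenated trial-type matrix) with **population** standard
deviation (ddof = 0, configurable); zero-variance neurons cannot be
standardized and are dropped with a log entry. Condition averages (lever ×
i-value stratum) are means over neurons of per-neuron trial averages, with
per-bin paired t tests across neurons corrected by Benjamini–Yekutieli FDR
across bins — BY rather than BH because neighboring time bins are strongly
dependent after smoothing.

The neuron-exclusion rule for the state-space analysis retains a neuron iff
it fires at least one spike inside the analysis window of the trials of
every run trial type present (third and fourth trials counted as separate
types).

## State space and distances

The eight trial-type matrices (101 bins × N neurons, trial-averaged —
trial-averaging before concatenation is implied by the 101-rows-per-type
structure; a single-trial variant is possible by passing per-trial matrices
but is not the default) are concatenated to 808 × N, z-scored per column,
and decomposed with full-spectrum PCA. Component signs are fixed by forcing
each component's largest-magnitude loading positive, making the
decomposition deterministic. Trajectories are the per-type score rows in the
top-3 space; the distance between a run's third and fourth trials is the
per-bin Euclidean norm of the trajectory difference (the diagonal of the
full pairwise distance matrix), and its mean over bins is the summary
statistic. Per-session analyses rebuild the space from that session's own
concatenated matrices. Group-level contrasts (time × run type × delay) are
expressed as a tidy long table feeding the Greenhouse–Geisser-corrected
repeated-measures ANOVA, with Scheffé pairwise post hocs and per-bin BY-FDR
t tests.

## Statistics module

Multiple-testing corrections, the RM-ANOVA (via pingouin, GG epsilon on all
within effects; a two-level factor has ε = 1 and reproduces the paired t²),
and the standard tests (paired/two-sample t, Wilcoxon rank-sum and
signed-rank, two-sample KS) delegate to scipy/statsmodels/pingouin; this
package pins the variants (two-sided throughout; rank tests switch from
exact to normal approximation at n = 25). The BY adjustment is additionally
checked against an independent step-up oracle in the tests.

## Synthetic data: what it does and does not emulate

`SynthSpec` drives both generators from one seed. Behavior: a softmax agent
at `k_true = 0.25 /s`, temperature 1–2, three sessions per delay over
{0, 1, 2, 4, 8, 16} s with the standard 30-trial/35-min limits. Neural: 60
neurons (desk-scale; real sessions carry hundreds) with gamma-distributed
baselines around 5 Hz, independent uniform lever-specific gains (mean 2 Hz)
creating distinct immediate/delay population patterns, and Poisson spiking
on a 10 ms grid. Two pre-choice templates emulate the two encoding regimes:
`stable` (modulation constant across the −19…+1 s window, the
short-delay/procedural regime) and `ramping` (modulation rising linearly
over the final 8 s before the choice, the long-delay/deliberative regime).
On Change runs the fourth trial adds `effect_size_hz` (default 3 Hz) to a
fixed random half of the population; the run's lever pattern is used for
both the third and fourth trials, so at zero effect size Change and
Fail-to-Change are statistically identical by construction.

`run_coverage_session` realizes a scripted choice sequence containing a
balanced set of all four run types with 30 s trial spacing (so peri-choice
windows never overlap); it exists because a stochastic agent does not
guarantee per-session coverage of all eight trial types.

What passing tests on this generator show: the pipeline recovers planted
discount rates, planted population-pattern updates (distance contrast
monotone in the offset), and planted temporal structure (flat versus rising
pre-choice distance profiles). What they do not show: robustness to
correlated noise, non-Poisson firing, drift, unbalanced trial counts, or
sorting artifacts — real recordings have all of these.

## Problem sizes and numerical choices

Tests and the acceptance script run sessions of ~50–70 trials, 40–60
neurons, 100-seed recovery sweeps and 1,000-replicate calibration loops —
sizes chosen so the full suite completes in well under a minute while
keeping Monte-Carlo standard errors small relative to the tested bands.
Tolerances: exact oracle equivalences at 1e-12; optimizer-dependent
comparisons at 1e-4–1e-6; stochastic recoveries at 10% bands or seeded
fixed draws.

## Known limitations

* The hyperbolic fit constrains k ≥ 0; datasets genuinely better fit by
  negative k (increasing value with delay) will be pinned at 0.
* The Gaussian smoothing option at σ = 10 ms under 200 ms bins is nearly a
  no-op; meaningful Gaussian smoothing requires σ on the order of the bin
  width.
* The per-bin FDR t tests treat neurons (or sessions) as exchangeable
  replicates; hierarchical structure (neurons within animals) is not
  modeled.
* PCA is linear; rotational or high-dimensional nonlinear dynamics are
  summarized only insofar as they project onto the top three components.
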