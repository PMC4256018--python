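# Methods

This note documents the models, estimators and numerical choices behind
`ornpn`, and what the synthetic data can and cannot show about real
recordings.

## Response model and units

Time is in milliseconds with the stimulus valve opening at t = 0; the odour
reaches the antenna after a transport time `T_t` (Gaussian, mean 180 ms,
SD 13 ms); rates are in AP/s; doses `C` are log10 of the load in ng.

Each neuron is the 6-parameter vector `(F_M, C_1/2, n, L_0, λ, L_m)`:

* firing rate `F(C) = F_M / (1 + 10^{n (C_1/2 − C)})` (Hill in log dose);
* first-spike latency `L(C) = max(L_0 − λC, L_m)` (line with a floor).

Derived characteristics use the response criterion `F_0 = 5 AP/s`:
`C_0`, `C_s` are the doses where `F` crosses `F_0` and `F_M − F_0`
(closed forms in `ornpn.doseresponse`, verified against root finding to
1e-9 log units), `ΔC = C_s − C_0`, `L_M = L_0 − λ C_0`, `ΔL = L_M − L_m`.
`ΔC` is undefined when `F_M ≤ 2 F_0`.

The evoked spike train is regular: first spike at `T_t + L(C)`, interspike
interval `1000/F(C)` ms, continuing to the end of the window.  An optional
Gaussian ISI jitter exists for robustness experiments and is off by
default.

## Spike-train metrics

The instantaneous rate f(t) is a Gaussian-kernel estimate (SD 50 ms,
unit area per spike in seconds, truncated at ±4 SD, 1-ms grid).  `F_raw` is
the height of the response peak of f inside `[T_t − 40, T_t + 1000]` ms;
two peak rules are provided: the first local maximum above the
pre-stimulus mean (appropriate for multiphasic responses, where the first
excitation peak — not the rebound — is wanted) and the global maximum
(the default in the pipeline, because the synthetic responses are
monophasic sustained plateaus on which background ripples would
masquerade as early peaks).

Significance uses bump counting: a response is significant when fewer than
5% of the local maxima of the neuron's own spontaneous rate function reach
`F_raw`.  Bumps are strict local maxima on the 1-ms grid; plateaus count
once, at their first grid point.

Control (solvent / clean-air) puffs evoke responses of their own (mean ±
SD 15 ± 10 AP/s in ORNs, 59 ± 28 AP/s in PNs).  Each neuron's control mean
`F_c` is subtracted from every raw response: `F = F_raw − F_c`.  For the
correction to make sense the generator superposes the control transient on
*every* trial, not only control trials.

Response time `T` is the first spike attributable to the response;
`L = T − 180` (negative values are legitimate when the transport time runs
short).  Two attribution rules exist:

* the conservative rule (`response_time`): skip spikes earlier than
  `T_t − 3·13` ms, optionally require the onset to start a burst;
* the half-rise rule (`attribute_response_time`, used by the pipeline): a
  rate step of height h smoothed by a Gaussian kernel crosses
  baseline + h/2 exactly at the step time, so the crossing of
  `F_c + (F_raw − F_c)/2` locates the onset; the response time is the
  first spike near that crossing whose following interspike gaps are
  within ~2 evoked intervals.

Responses weaker than ~25 AP/s over control cannot be timed reliably
against the background and the control transient, so latencies only enter
line fits above that rate.  Rates below `F_0` are anchored at zero in the
Hill fits (kernel bumps of isolated extra spikes on the control plateau
are not a response); the ambiguous band `F_0..2F_0` is dropped.

## Fitting

`HillModel.fit` is bounded nonlinear least squares (`scipy.optimize.
curve_fit`) with a 5-point multistart (Hill slopes 0.5/1/2 at the median
dose, unit slope at the quartile doses) and best-RSS selection; bounds are
`F_M ∈ (0, 2·max F]`, `n ∈ (0.05, 10]`, `C_1/2` within the dose range ± 3.
A fit is *well estimated* only if the fitted curve reaches ≥ 85% of `F_M`
at the highest tested dose — otherwise the asymptote is an extrapolation
and the fit is excluded from population medians (mirroring the practice of
only trusting maxima observed within the tested range).

`LatencyModel.fit` sets `L_m` to the shortest measured latency, initialises
`(L_0, λ)` by ordinary regression on the points off the floor (excluding
observations within 5 ms of the running minimum at the two highest doses),
then refines both against the floored model `max(L_0 − λC, L_m)` with a
robust (soft-L1, scale 20 ms) loss, so floor points no longer attenuate
the slope and heavy-tailed attribution errors do not drag the line.  The
slope is flagged unidentified when fewer than two points sit off the
floor, or when it comes out non-positive.

Under multiplicative CV-0.33 rate noise, the median fitted `F_M` keeps a
~10% upward bias (the noisy top doses dominate the asymptote); the ED50
and Hill slope are essentially unbiased.

## Population statistics

Per-dose distributions are ML-fitted normals/lognormals with a one-sample
KS test against the fitted CDF.  The heterogeneity line regresses per-dose
SD on per-dose mean with zero intercept below a breakpoint (default
100 AP/s — the SD grows proportionally below it, with CV ≈ 0.33, and is
flat above) and averages the SD above it.  Pearson correlations are
pairwise-complete, with `n`, `λ` and `L_M` log-transformed first (their
marginals are lognormal); raw p-values are reported, with an optional
Benjamini–Hochberg switch.  `estimate_multinormal` returns the sample mean
and covariance of the six parameters on the internal scale (natural logs
for `n`, `λ`), with a nearest-PSD projection when sampling noise makes the
covariance indefinite.

Quantile curves couple marginal quantiles: the "10% most responsive" curve
pairs the 90% quantile of `F_M` with the 10% quantiles of `C_1/2` and `n`;
the "fastest" latency curve pairs the 10% quantiles of `L_0` and `L_m`
with the 90% quantile of `λ` (the steeper slope reaches the floor sooner).

## Variance decomposition

Two independent axes: stimulus vs biological, and irregularity (within
one unit) vs heterogeneity (across units), giving

    σ²_Ti = σ²_Si + σ²_Bi,     σ²_Th = σ²_Sh + σ²_Bi + σ²_Bh.

From a series × repetitions design (same cartridge within a series,
different identically prepared cartridges across series), the pooled
within-series variance estimates total irregularity, and the one-way
random-effects ANOVA estimator `(MSB − MSW)/n₀` the pure between-series
variance.  The total heterogeneity fed into the decomposition is the
between-series variance *plus* the within variance, because a single
measurement on a new unit carries that unit's irregularity once; the
across-unit total therefore also carries the stimulus irregularity once,
which adds `σ²_Si` to the recovered biological heterogeneity (negligible
at the default noise levels, where the stimulus irregularity SD of
4.43 ms is three times smaller than the 13.3 ms heterogeneity).
Negative component estimates clip to zero with a warning.  When only
published CVs are available, components combine on the CV² scale under a
common-mean assumption (`cv_decomposition`, flagged as an approximation).

## Transfer functions

The closed forms (rate: Hill-like with the extra "−1" in the denominator;
latency: affine with slope `λ_P/λ_R`, floored at `L_Pm`) are the normative
implementations and are tested to 1e-9 against explicit dose elimination
over parameter sweeps, avoiding the singular endpoints (curves are
reported over `[~0, 0.99 F_RM]`).  The transfer depends only on the ED50
*difference*: the absolute positions of the two curves on the dose axis
are not recoverable from it.  The ORN input driving the PN to half-maximum
is `F_RM / (1 + K^{−n_R/n_P})`.

## Convergence simulator

`N` (default 7000 — ~90 antennal segments × ~80 sensilla × 1 responsive
neuron) parameter vectors are drawn from the population model, each
producing a regular evoked train plus a regular spontaneous train with
random phase at a lognormal rate; the PSTH is the 10-ms-binned summed
count.  Per-neuron randomness uses one substream per neuron spawned from
the master seed, so enlarging `N` leaves earlier neurons unchanged.
Spontaneous and evoked activity superpose additively.

Two spontaneous-rate conventions exist, because the lognormal law
(μ = 1.23, σ = 0.71, mean 4.40 AP/s) and the stated population total
(27 000 AP/s, i.e. 3.86 AP/s per neuron) disagree by ~14%:
`spont_total_ap_s` rescales the draws to a fixed population total and is
used for all detection analyses (baseline ~270 counts per 10-ms bin);
leaving it unset keeps the raw lognormal law.  The discrepancy is
documented, not resolved.

When a train's expected in-window spike count is below one, its onset
spike is emitted with that probability instead of deterministically:
otherwise every neuron whose Hill extrapolation gives 0.01–1 AP/s many
log units below its ED50 would contribute a deterministic onset spike,
inflating the sub-threshold population excess ~20-fold.

Detection requires the summed rate to exceed `B + r√B`.  The threshold
dose estimator averages PSTHs over several populations, smooths with a
50-ms moving average, and compares the peak *excess over the ensemble's
own pre-arrival baseline* to `r√B` — at r = 3 the margin is only ~1.8% of
the baseline, far below single-PSTH bin noise, so the ensemble averaging
and baseline subtraction are what make the crossing measurable.

Under the sustained-train model the summed rate is monotone to a plateau
(there is no adaptation), so the "response maximum" is operationalised as
the time after stimulus arrival at which the summed rate first reaches
95% of its plateau (~195 ms at 1 log ng under the default model: the rise
reflects the gradual recruitment of neurons in order of latency).

`fraction_faster_than` evaluates P[L(dose) ≤ L_ref] either analytically
(Gauss–Hermite quadrature over the lognormal `λ`, bivariate-normal CDF
for the conditional `(L_0, L_m)` law, handling the floor exactly) or by
Monte Carlo; the two agree within Monte-Carlo error.

## The default population models are a reconstruction

The covariance table of the original 6-parameter distribution is not
published, so the defaults in `ornpn.defaults` are rebuilt from summary
statistics: medians `F_M` 163 / 62 AP/s and `n` 0.81 / 0.79 (ORN / PN);
ORN `C_1/2` = 1.35 chosen so the median threshold dose is −0.50 log ng,
PN `C_1/2` = −1.35 encoding the 2.7-log-unit (≈500-fold) sensitivity
shift; latency lines (150 − 28C, floor 60) and (58 − 18.2C, floor 43)
solved from the median maximum latencies (164 / 107 ms), latency ranges
(104 / 64 ms) and the 0.65 latency-transfer slope — this set also
reproduces the transfer floor engaging below an ORN latency of ~127 ms.
Spreads come from the per-dose CV structure (per-dose latency CV ≈ 0.43
→ σ(L_0) = 60 ms; rate-SD plateau ≈ 35 AP/s → σ(F_M) = 35; the 2% / 98%
ED50 contrast at 0 log ng → σ(C_1/2) ≈ 0.66–0.70), and the lognormal
spread of `n` is constrained to σ = 0.20–0.25 by the requirement that the
population PSTH stays at baseline 5–6 log units below the median ED50
(wider spreads leak shallow-slope responses there).  Only the
significantly correlated parameter pairs carry non-zero correlations
(ORN: C_1/2–L_0 +0.4, L_0–λ +0.5, L_0–L_m +0.5; PN: C_1/2–n −0.45 and
the two latency pairs).  Control-transient latencies (~150 ms ORN,
~120 ms PN) and trial-level irregularity CVs (0.16 rate, 0.34 latency)
complete the generator.

## What the synthetic data does not capture

* Evoked trains are strictly regular and sustained: no phasic-tonic decay,
  no PN inhibition/rebound phases, no adaptation — so the PSTH plateaus
  instead of peaking, and the first-peak logic is exercised only on
  constructed fixtures.
* `L_m` is defined as the shortest *measured* latency; as an extreme-value
  statistic under the 0.34 trial CV it underestimates the generating floor
  by ~25%, and `ΔL` inherits the complementary bias.
* The PN floor (43 ms) lies only 15 ms below the PN latency at 0 log ng
  (58 ms), so line and floor are barely separable at realistic noise: the
  recovered PN latency characteristics (`L_M`, `ΔL`) overshoot by
  ~20–40%, and the fitted latency-transfer slope lands near 0.8 rather
  than 0.65 (the pooled ORN λ attenuates ~25% because sensitive,
  steep-λ neurons expose few off-floor doses).
* The fast-ORN fraction ahead of the typical PN is ~5% but essentially
  flat across the PN dynamic range under this reconstruction (the ORN
  latency distribution and the PN reference shift together), whereas a
  decreasing trend is expected under the original covariance.
* Measured sensitivity separations (ED50, fold change) run ~10% above the
  generating 2.7 log units because sub-threshold rate measurements carry
  a small positive floor from kernel bumps on the control plateau.

Passing tests therefore demonstrate correctness of the estimators and the
algebra, and faithful recovery of rate-side parameters (within ~5–10%)
under the stated noise; latency-side characteristics carry the biases
listed above, which are properties of the estimation problem, not of the
code path.

## Problem sizes

Default analyses use 38 ORNs (6 doses, 1 trial each) and 47 PNs (5 doses,
2 trials each) per session with 4 control trials per neuron; the
acceptance script pools 3 sessions.  Recovery suites use 200 replicates
(fits) and 300–500 replicates (variance design); population simulations
use the full N = 7000 with 600–1000 ms windows and 8–12 Monte-Carlo
populations per detection estimate.
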