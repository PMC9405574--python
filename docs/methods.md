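# Methods

## Data-generating model

Ground truth comes from the simplified Izhikevich system

    dv/dt = 0.04 v² + 5 v + 140 − u + I(t)
    du/dt = a (b v − u),        if v ≥ 30 mV: v ← c, u ← u + d,

integrated by forward Euler at dt = 0.25 ms.  The stored sample at a spike is
clamped to the 30 mV peak and the reset applies before the next step, so the
trace carries its own ground-truth spike train.  Integration is plain Python
over the time loop (the reset makes the recursion inherently sequential);
an update that leaves |v| > 10⁶ without reaching the reset raises an error
naming the behavior and step.

Twenty behaviors (labels a–t) are shipped in `data/default_catalog.yaml`:
per behavior the hyperparameters (a, b, c, d), initial state (u₀ = b·v₀
unless stated), sample count and the injected-current protocol.  Most
constants are the classic published values for this behavior set.  Three
behaviors are demonstrated in the original publication's code with a
*modified* right-hand side, which is outside this package's scope (only the
simplified system above is integrated), so their protocols were re-derived
under the standard equations:

* **class 1 excitable (g)** — a current ramp to 30 over the stimulated
  window; with b = −0.1 the quasi-static rheobase is ≈ 22.6, so firing
  starts mid-ramp with a continuously increasing rate;
* **integrator (l)** — tonic-spiking-type parameters (b = 0.2, rest −70 mV,
  saddle ≈ −50 mV) with 2 ms pulses of amplitude 8: one pulse or a pair
  10 ms apart stays subthreshold, a pair 3 ms apart sums to threshold;
* **accommodation (r)** — b = 0.2 with a slow ramp to 3.5 (below the
  quasi-static rheobase ≈ 4, which the recovery variable tracks) followed by
  a brief 6 ms pulse of amplitude 8 that outruns the recovery (frozen-u
  rheobase ≈ 2.25) and fires once.

Two further constants differ from the historical demo values because the
durations here are 10–50× longer: the inhibition-induced-bursting reset
increment is d = +2 (the canonical −2 makes the recovery variable, already
unstable for a < 0, run away over long windows), and the depolarizing
after-potential reset uses d = −16 with a 2 ms, 20-amplitude pulse so the
after-potential peaks below threshold at this integration step.

Protocol times are stored as (fraction, offset) pairs resolved as
`fraction·T + offset`, so stimulus onsets scale with the duration while
pulse widths and dynamically critical gaps (the 40 ms resonant interval of
the resonator, pulse-pair spacings, inhibition windows) stay absolute in
milliseconds.  Default durations are chosen per behavior so that the full
two-channel Fourier design has its reference column count (e.g. 20,000
samples for tonic spiking); a global `scale` factor multiplies every sample
count, and segments that fall outside a shortened window are clipped.  The
default catalogue yields exactly 9 one-spike and 11 multiple-spike behaviors
at scales 1, 0.5 and 0.1, and halving dt leaves every one-spike count exact
and every multiple-spike count within a few percent (the Euler-convergence
smoke test asserts ≤ 10 %).  Traces with no spikes are rejected from
benchmarking with a warning.

## Designs

All families regress the membrane potential (including the clamped spike
peaks) on two teacher-forced channels: the injected current I(t) and the
ground-truth spike indicator lagged by one sample, S(t−1).

* **Lagged (SRM/RSRM/PCR):** columns I(t−s), s = 0..J and S(t−q), q = 1..Q;
  rows restricted to samples where all lags exist.  Default J = Q = ⌊n/8⌋,
  chosen so that every stimulus event (onsets at 0.1–0.3 T) falls inside the
  usable window at every scale while keeping the parameter count within the
  order of magnitude of a lag-per-sample model.
* **Fourier (SSRM/RSSRM):** each channel multiplied elementwise by every
  non-constant column of the n×n orthogonal Fourier basis (sin and cos
  carry separate coefficients; the alternating column is included for even
  n), i.e. n−1 columns per channel, 2(n−1) in total.  On the support of its
  channel this set spans the sample space, which is why the unpruned model
  interpolates the training signal; off-support rows are all-zero and are
  predicted as the intercept, so pulse-driven behaviors keep a nonzero
  training RMSE no matter how many columns survive.
* **Raised cosine (RCR):** half-period cosine bumps, centers equally spaced
  in the stretched coordinate a(t) = log(t + ψ) (ψ = 1 sample by default),
  support two center-spacings to each side, partition of unity away from
  the edges; an odd budget splits as ⌈k/2⌉ + ⌊k/2⌋ over the two channels.
* **PCA (PCR):** the first k principal-component scores of the centered
  (not scaled — the lagged regressors share units) lagged design; the
  cumulative explained-variance fraction is reported.

## Fitting

Every family minimizes ½Σ(u−û)² + λ₁Σ|w| + λ₂Σw² with an unpenalized
intercept and the shared ridge λ₂ = 0.01 applied to internally standardized
columns (the two channels differ in scale by orders of magnitude; the
penalty acts on the standardized weights and the fit is invariant to column
rescaling).  The ridge-only problem is solved in closed form, through the
kernel (dual) system when columns outnumber rows.  With λ₁ > 0 the solver is
cyclic coordinate descent (scikit-learn's, via alpha = (λ₁+2λ₂)/n,
l1_ratio = λ₁/(λ₁+2λ₂)), stopping tolerance 1e−4 and at most 10⁴ passes;
tests pin the solution to the closed-form soft-threshold solution on
orthogonal designs and to the direct ridge solve at λ₁ = 0.

The pruned families fix their parameter budget by a search on log λ₁: a
warm-started path walks down from λ_max = max|Xᵀ(y−ȳ)| (all weights zero) in
factors of 0.7 until the nonzero count reaches the budget, then bisects the
bracket until the count is within ±2 % (at least ±1) of the target or the
bracket collapses; the closest fit is kept and flagged if the slack was not
met.  After the search fixes *which* parameters survive, their values are
re-optimized by a ridge-only refit on the active set (relaxed-lasso style;
`refit=False` restores the shrunk weights).  The L1 search decides the
model's support; the refit removes the shrinkage bias that would otherwise
dominate the pruned models' potential error.  The reported `objective_value`
is evaluated at the adopted weights.

Fitting and evaluation both use the entire trace (teacher forcing, no
train/test split): the question studied is how much accuracy survives
parameter reduction, not generalization.

## Spike conversion and scoring

Predicted potentials become spike trains in three steps.  (1) With true
firing proportion r and inflation coefficient β, the threshold is the
empirical (1 − rβ) quantile (linear interpolation) of the predicted
potential — e.g. r = 10 %, β = 1.5 puts the threshold at the 85th
percentile — and a sample spikes iff it exceeds the threshold and is a local
maximum (strictly above its left neighbour, not below its right one, so a
plateau yields one spike; endpoints never spike).  (2) The maximum tolerance
τ_max is the smallest multiple of dt at which every spike of the smaller
train finds a distinct partner within τ; matching is greedy over the two
time-sorted trains (match when within τ, else advance the earlier side),
which is a maximum matching for points on a line, so feasibility is monotone
in τ and the smallest τ is found by bisection on the dt grid — identical to
an upward sweep.  The search upper bound is max(|max p − min t|,
|max t − min p|), at which full matching always holds.  (3) Matched
predicted spikes are replaced by their true partners' times and the train is
re-gridded; F1 is computed sample-wise on this tolerance-adjusted train.
β is selected per cell from its family's grid — 11 uniform points on
[1, 1.5] for the full models, 60 log-spaced points on [1, 270] for the
pruned/reduced ones, candidates with rβ ≥ 1 skipped — maximizing the
adjusted F1 with ties to the smallest β.  τ_max is capped at 30 ms for PCR
and RCR only (flagged when binding); the van Rossum distance (closed
pairwise exponential form, τ = 1 ms, times in ms) is always computed on the
unadjusted detection output, since its cross terms already compare all
spike pairs.

Degenerate conventions: a detection with no spikes scores F1 = 0 and leaves
τ_max undefined (NaN in records); two identical trains — including two
empty ones, which is logged — score precision = recall = F1 = 1.

## Benchmark

Each behavior × model cell runs design → fit → predict → convert → score;
the ground-truth trace itself is pushed through the same scoring pipeline as
the reference row (its quantile threshold falls below the 30 mV clamp
samples, so it recovers itself exactly: RMSE 0, VRD 0, F1 1, τ_max 0).
Failures are isolated per cell.  Class averages (all twenty / 9 one-spike /
11 multiple-spike) are arithmetic means; model rankings per metric use
competition ranking (ties share the minimal rank; lower is better for RMSE
and VRD, higher for F1).  Default per-behavior parameter budgets average
≈ 100 at full scale and shrink proportionally with `scale`.  VRD below 1e−6
is displayed as 0 in written tables (raw values stay in the records); the
persisted tables exclude wall-clock columns and are byte-identical across
reruns of the same configuration.  Wall-time instrumentation is recorded in
the in-memory records only and is hardware-dependent; memory profiling is
not implemented.

## Problem sizes and determinism

The shipped experiments (acceptance script, heavy tests) run at
`scale = 0.1` — 165 to 2,500 samples per behavior, budgets of 1–20 surviving
parameters — where a full sweep of the spectral models over all twenty
behaviors takes on the order of a minute on one core.  Everything in the
pipeline is deterministic: the generator has no noise, coordinate descent
uses cyclic updates, and the PCA uses a fixed random state; the acceptance
script's `--seed` is logged with the outputs.

Consequences of the reduced scale worth knowing: a missed 30 mV spike peak
(always off the stimulus support for pulse-driven behaviors) weighs √10 ≈ 3×
more in RMSE than at full length, and budgets of 1–2 parameters make single
behaviors brittle (the pruned spectral model finds no detectable local
maximum at all on the rebound-spike behavior, scoring F1 = 0 there while
still averaging ≈ 0.94 over the twenty).  What passing tests show is
therefore the *structure* of the comparison — interpolation of the full
spectral model, graceful degradation under pruning, the pruned spectral
model beating the pruned lagged model — not the paper-scale magnitudes of
every metric.

## Known limitations

* Teacher forcing only: spike-history features always come from the ground
  truth; free-running generation is out of scope.
* The generator emulates noiseless, single-neuron, constant-segment/ramp
  stimuli; real recordings (noise, drift, richer stimuli) are not modeled,
  and conclusions about robustness to them are not supported by these tests.
* The maximum-tolerance matching is reconstructed from a prose description;
  the greedy rule is verified against brute-force optimal matching on small
  sets but other disciplines (e.g. globally optimal assignment by total
  displacement) would give different τ_max on ties.
* Elastic-net and SCAD penalties, network composition and fits to
  experimental recordings are out of scope.
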