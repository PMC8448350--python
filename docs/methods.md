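# Methods

## Paradigm generation

Each artificial language has 28 distinct CVCV pseudowords: one A word and
one C word per dependency (A1→C1, A2→C2) and 24 X words, of which 12 are
shared between the dependencies and 6 are unique to each.  Word forms are
sampled from Spanish-legal consonant/vowel inventories; since no
computation depends on letter identity, no attempt is made to exclude
real-word collisions.  The NADs block enumerates all 2 × 18 AXC phrases and
presents each twice (72 trials); with each A preceding its 18 X words
equally often, the empirical A→X transition probability is exactly 1/18.
The Random block pairs the 24 X words into 48 distinct XX sequences — each
X exactly twice in first and twice in second position, never twice within a
phrase — and ends half with C1 and half with C2; each phrase is presented
twice (96 trials).

Trial order is pseudorandom under two mild interleaving constraints: no
identical phrase on consecutive trials, and no more than 3 consecutive
trials of the same dependency (NADs) or the same final word (Random).  The
sequencer is a greedy constrained shuffle with restart; all orderings are
deterministic per seed.  Counterbalancing assigns participants round-robin
to the 8 cells of block order × monitored target (C1/C2) × language-to-block
assignment.

Timing is configuration, not inference: phrase duration 1,460 ms and a
fixed 1,000 ms inter-trial interval (or a 1,500–3,000 ms uniform jitter for
scanner-style schedules).  The stated per-word duration (385 ms plus 100 ms
gaps) would sum to 1,355 ms; the 1,460 ms phrase figure is adopted as the
default since it is the one tied to trial duration.  Scheduled onsets are
the phrase-plus-ITI grid; response-time variability within the response
window is not modeled in the schedule.

## Learners

All learners start from V = 0 for every word at block onset (a new language
per block makes any other prior unmotivated) and update on *every* trial,
including trials later excluded from fitting — exposure, not the response,
drives learning.  The TD learner applies, in order: ∂¹ = V(w₂) − V(w₁);
V(w₁) += α∂¹; ∂² = R − V(w₂); V(w₂) += α∂²; V(w₁) += α∂²γ, with R = +1 for
target-final phrases and −1 otherwise.  For α, γ ∈ [0, 1] each TD update is
a convex combination of current values and R, so |V| ≤ 1 always.  The RW
learner updates both of the first two words by the single compound
prediction error R − (V(w₁) + V(w₂)); because two cues share one error, RW
values can transiently overshoot [−1, 1] at extreme learning rates, so the
recorded prediction p = |V(w₁)| (taken *before* any update, i.e., the value
available at phrase onset) is clipped to [0, 1], the scale the likelihood
requires.  The chance model predicts 0.5 — the midpoint of the
transformed-RT codomain — on every trial.

## Likelihood and optimization

RTs from included trials (correct responses under 1,000 ms) are z-scored
per participant *per block* (the learner is run per block, and cross-block
speed differences would otherwise leak into the fit), then mapped to (0, 1)
by xRT = 1/(1 + exp(zRT)).  The per-trial likelihood is Δₜ = 1 − |xRTₜ − pₜ|
and the block log-likelihood is Σ log max(Δₜ, 1e−12); with Δ ∈ [0, 1] this
behaves as a proper per-trial likelihood and makes "fit index 1 = exact
fit" hold identically.  The model-fit index is 1 − LLE_model/LLE_chance,
computed on the same included-trial set for both models.

Optimization is Nelder–Mead from a fixed deterministic lattice of start
points (5 × 2 over (α, γ) for TD; 10 over α for RW), with parameters
clamped to the unit square inside the objective and ties broken by first
occurrence.  Deterministic restarts make every fit bit-reproducible; the
test suite verifies that the restart scheme reaches at least the optimum of
a 101 × 101 grid search.  TD ↔ RW comparisons use a paired t test on
per-participant fit indices with Cohen's d_z (mean of differences / SD of
differences), labeled as such in the output.

## Group statistics

The 2 × 2 repeated-measures ANOVA (Structure × Target) is computed from
participant-wise contrast scores, which is exact for 2-level factors: each
within effect is the squared paired t of its contrast, with
partial η² = F/(F + df_den) for 1-df effects.  The block-order check adds
Order as a between-participants factor: the Order main effect is a one-way
ANOVA on participant averages, and each within effect and its Order
interaction come from a two-group linear model on the contrast scores
(unweighted means, pooled error).  This in-package implementation exists
because no installed Python package covers the 2-within × 1-between mixed
design; it is validated against an explicit sums-of-squares oracle and
against pingouin for the purely within design.  The NADs effect is the
unweighted average of a participant's two Random cell means minus the two
NADs cell means, so the cohort NADs effect coincides exactly with the
ANOVA's Structure mean difference.  Participants with an empty design cell
are dropped listwise with a warning.

Learning slopes use the mixed model
rt ~ condition + trial + condition:trial + TNT + (1 | participant), REML,
with Random and NoTarget as reference levels and trial 1-based and
uncentered within block, so the interaction coefficient β_diff is the
NADs-vs-Random difference in ms per trial.  Estimation is delegated to
statsmodels MixedLM; degrees of freedom for the fixed-effect t tests use
the Satterthwaite approximation, computed in-package from the closed-form
random-intercept REML criterion (Woodbury per-group algebra;
finite-difference gradient of Var(β̂) over the variance components and
finite-difference REML information).  This component is hand-written
because no installed Python package provides Satterthwaite df; it
reproduces R's lmerTest to ~5 significant figures on reference fits.
Singular fits (random-intercept variance at the boundary, or zero residual
variance on noiseless fixtures) are flagged and fall back to residual df,
labeled accordingly.

## Synthetic cohorts

The generator is the near-inverse of the fitting assumptions, which makes
the machinery's own assumptions directly testable: per participant a TD
learner with (α, γ) drawn uniformly from configured ranges is run over both
blocks; trial-wise predictions receive Gaussian noise on the (0, 1) scale,
are clamped to [ε, 1 − ε], and are mapped to milliseconds by
RT = rt_mean + rt_sd · log(1/xRT − 1).  Defaults: 19 participants (the
behavioral cohort size), rt_mean 600 ms and rt_sd 100 ms (plausible for a
speeded detection task with a 1,000 ms inclusion cutoff), prediction noise
SD 0.1, error rate 5 %, timeout rate 2 % (typical low lapse rates;
missing-at-random), γ drawn from [0.5, 0.9] and α from [0.05, 0.35].  The
clamp ε = 0.01 bounds |zRT| at log(99) ≈ 4.6 and hence keeps generated RTs
positive (600 ± 460 ms); trials pushed beyond the 1,000 ms cutoff are
excluded by the standard filter, as in real data.

One property of this design deserves emphasis: the generative map is not
exactly invertible by the fitting pipeline, because fit-time z-scoring
would have to reproduce the raw log(1/xRT − 1) values, which happens only
if they are already standardized — and the TD trajectory does not make them
so.  Recovery through RT space is therefore consistent but not exact even
at zero noise (α correlates with truth above 0.95; γ is attenuated), while
recovery on the prediction scale — bypassing the RT mapping — is exact and
is what the self-consistency checks assert.  Consequences: α's recovery
error is *not* monotone in noise (its zero-noise floor is standardization
distortion, not estimation noise), whereas γ's error and the mean fit index
degrade monotonically.

What the generator does not emulate: target-detection motor speed-up
(targets and non-targets are generated symmetrically, so the Target main
effect is null in synthetic data, unlike in real cohorts), attention drift,
fatigue, and any non-Gaussian RT tail structure beyond what the logistic
inverse induces.  Passing tests therefore certify the analysis chain, not
the realism of the RT law.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's native sizes (72/96
trials; cohorts of 6–20 participants; 100 replicates for CI coverage), a
scale chosen to keep the whole suite in the order of a minute.  Nelder–Mead
tolerances are xatol 1e−4 / fatol 1e−7; the likelihood floor is 1e−12; the
grid oracle uses a 101 × 101 lattice.  Degenerate inputs are rejected
loudly: fewer than 2 distinct RTs (no z-score), fewer than 10 included
trials (no fit), constant prediction traces (no z-scored regressor), fewer
than 3 participants (no paired test or ANOVA), single-level order factors.
Paired comparisons with numerically constant differences return t = 0 when
the common difference is zero (a true null) and a flagged NaN otherwise.

## Known limitations

* Scheduled onsets ignore within-trial response-time jitter.
* The RT generative law is the analysis' own inverse transform, not an
  independent chronometric model; conclusions about real RT distributions
  require real data.
* The Satterthwaite machinery covers the random-intercept model only (the
  only random-effects structure the slope analysis uses).
* XLSX ingestion is layout-agnostic via ColumnMap but assumes trial-level
  rows; binned or aggregated sheets cannot be expanded.
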