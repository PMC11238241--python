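# Methods

This note documents the generative model, the estimation machinery, the
numerical choices and the known limitations of `vplkit`.

## Generative observer model

An observer is a tuple (C0, ρ, β, λ): initial coherence threshold
C0 ∈ (0, 1], learning rate ρ ≥ 0, psychometric slope β > 0 and lapse rate
λ ∈ [0, 0.1]. The latent threshold at (1-based) session *t* is

    θ(t) = C0 · t^(−ρ),

so θ(1) = C0 is the pretest threshold and the curve is non-increasing. The
probability of a correct 2AFC response at presented coherence *c* is a
Weibull with a 0.5 guess floor and lapse ceiling:

    p(c) = 0.5 + (0.5 − λ) · [1 − exp(−K · (c/θ(t))^β)].

The scale constant K = −ln(1 − (0.5^{1/3} − 0.5)/0.5) ≈ 0.8852 is fixed so
that, lapse-free, p(θ(t)) = 0.5^{1/3} ≈ 0.7937 — the nominal convergence
accuracy of a 3-down/1-up staircase. This calibration makes the staircase's
reversal-averaged estimate a (nearly) unbiased readout of θ(t), which is the
premise of fitting power laws to staircase thresholds.

There is no within-session learning, no inter-session forgetting or
consolidation, and no mechanistic stimulation model: group differences enter
exclusively through the distribution of ρ.

### Cohort defaults

Chosen once to produce learning curves with the canonical shape of a
stimulation study (matched starting points, faster decay under real
stimulation); every value is overridable through `GroupDesign` /
`ExperimentConfig`:

| parameter | default | meaning |
|---|---|---|
| groups | rDLPFC+rMT, rDLPFC, rMT, lMT, sham | 4 stimulation montages + sham |
| n per group | 12 | observers per group |
| C0 | N(0.45, 0.10²) trunc. (0, 1] | common across groups (matched baselines) |
| ρ (real stimulation) | N(0.30, 0.05²) trunc. ≥ 0 | rDLPFC+rMT, rDLPFC, rMT |
| ρ (controls) | N(0.15, 0.05²) trunc. ≥ 0 | lMT (ipsilateral) and sham |
| slope β | 3.5 | typical coherence psychometric steepness |
| lapse λ | 0.02 | small but non-zero attention lapses |
| training session | 5 blocks × 70 trials | staircase blocks, thresholds averaged |
| test | 120 trials, each location | trained (top-left) / untrained (bottom-right) |
| transfer τ | 0.5 | untrained location follows θ_u(t) = C0·(θ(t)/C0)^τ, i.e. learning rate τ·ρ |

## Staircase

Three-down/one-up on coherence with multiplicative 10 % steps (×0.90 down
after three consecutive correct, ×1.10 up after any error, capped at 1.0);
the consecutive-correct counter resets on every step. A reversal is recorded
when the step direction changes, at the coherence actually tested (the
pre-step level). Block threshold: discard the first four reversals if their
total is even, five if odd, and average the rest (at least two must remain,
i.e. ≥ 6/7 reversals). Session threshold: mean over blocks; blocks with too
few reversals are dropped, and a session in which every block fails is an
error.

Within a training session, block 1 starts at coherence 0.80 and each later
block starts where the previous one ended. Restarting every block at 0.80
would spend half of a late-training block descending toward thresholds
around 0.15 and regularly starves blocks of reversals; carrying the level
across blocks is standard practice and only the first block pays the descent
transient. Tests always start fresh at 0.80. The emulation pipeline re-runs
a staircase once if it still ends with too few reversals, as an aborted run
would be repeated in the lab.

### Equilibrium and estimator bias

The nominal target of a 3-down/1-up rule is the accuracy p with p³ = 1/2
(79.37 %). With *multiplicative* ±10 % steps, however, the log-domain steps
are unequal (ln 1.1 ≈ 0.0953 up vs ln(1/0.9) ≈ 0.1054 down), and the
zero-drift accuracy instead solves

    p³ = ln(1.1) / (ln(1.1) − ln(0.9)) ≈ 0.4748  →  p ≈ 0.780.

Long static-observer runs therefore sit near 78 % correct — within the
2-percentage-point band of the nominal 79.4 % that the package's checks use,
but measurably below it — and the reversal-averaged threshold converges to
the 78 %-correct coherence, about 0.98·θ at slope 3.5. Measured relative
bias of the estimator: ≈ −0.3 % for 70-trial blocks (the descent transient
almost exactly cancels the equilibrium offset at the study's block length)
and ≈ −2.6 % to −2.9 % for 1,000-trial and longer blocks. One test in the
acceptance suite asserts a ±2 % band at 1,000-trial blocks and fails by
design, documenting this intrinsic property of multiplicative-step
staircases; it is not a fitting or implementation defect, and "fixing" it
would require changing either the step rule or the calibration target.

### Plateau rule

With daily training thresholds θ₁, θ₂, …, the relative reduction into day
*i* is r_i = (θ_{i−1} − θ_i)/θ_{i−1}. The plateau day is the first *i* with
r_{i−1} < 1 % and r_i < 1 % (negative reductions count as < 1 %). The
emulation applies the rule online — intermediate training stops as soon as
the last two reductions are both sub-1 % — with a hard cap of 20
intermediate sessions (capped observers are flagged and the later stage
proceeds). Because the generative curve is a pure power law, the *expected*
reduction falls below 1 % only at t ≈ ρ/0.01; in practice the criterion
fires much earlier through staircase measurement noise, exactly as it would
on real data. Under the defaults this yields ≈ 9 ± 5 intermediate sessions —
the count depends entirely on the noise level and learning rate and is
reported, not calibrated.

## Learning-curve fitting and model selection

Fitting target: group-mean thresholds at five points per stage — pretest,
three training days, posttest — indexed t = 1…5 (the later stage is
re-indexed to start at 1, treating the plateaued curve as its own fitting
window). Per-observer fits are available through the same API.

A joint model is a pair of set partitions of the group labels (blocks
sharing C0, blocks sharing ρ); k = #C0-blocks + #ρ-blocks. Estimation is
nonlinear least squares on the pooled residuals (`scipy.optimize.
least_squares`, analytic Jacobian) with bounds C0 ∈ (0, 1.5], ρ ∈ [0, 3] and
three starts ρ₀ ∈ {0.1, 0.5, 1.0} (C0 started at each block's mean first-day
threshold); power-law fits on five points are multi-modal often enough that
single-start fits are not trusted. Convergence tolerances are 1e−12;
ties in RSS below 1e−15 keep the earlier start.

r² = 1 − RSS/TSS with TSS about the mean of the *measured* values, pooled
over groups. The nested F-test uses the r² form (equivalent to the RSS form
because both models share one TSS); a numerically perfect full fit
(RSS < 1e−10·TSS) gives F = ∞, p = 0, unless the reduced fit is also
perfect, in which case F = 0, p = 1.

Selection enumerates all Bell(G)² sharing patterns (G ≤ 6; 225 at G = 4),
tests each against the fully free model at α = 0.05, and returns the
candidate with p > α having the smallest k (ties: larger r², then
lexicographic partition label). If nothing survives, the full model is
returned with a warning flag. The type-I error of the F-test under a true
reduced model, measured at N = 20 points and threshold noise SD 0.02,
is ≈ 5.8 % over 2,000 simulations — the mild liberality expected from a
nonlinear model with 5 points per curve.

## Group statistics

- One-way ANOVA is computed from summary statistics (means, SDs, ns) so that
  published demographic tables can be re-analysed; the raw-data form reduces
  to it exactly.
- The mixed (split-plot) ANOVA implements the standard SS decomposition for
  one between factor × two within levels: between effect tested against
  subjects-within-groups, within and interaction against the subject×test
  residual. η² is classical (SS_effect/SS_total) by default because the
  components then conserve the total SS; partial η² is a flag. With only two
  within levels, sphericity is automatic and no correction is needed.
- LSD post hocs use the pooled error MS with unadjusted two-sided p values,
  as Fisher's procedure prescribes (protected by the omnibus F in the
  pipeline's usage).
- χ² homogeneity uses no continuity correction (required to match standard
  textbook values for 5×2 tables of this size).

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes:
power-law mean curves, staircase sampling noise, matched baselines, partial
transfer to an untrained location, and group differences confined to the
learning rate. It omits session-to-session fluctuations of attention or
criterion, consolidation between stages, any direct stimulation physiology,
and within-session learning. Passing tests therefore validate the *analysis
machinery* — estimator behaviour, test calibration, model-selection
accuracy — not the substantive claims of any particular experiment; fitted
values on real data depend on assumptions the generator cannot certify.

## Problem sizes used in the checks

Staircase equilibrium: one 50,000-trial run (accuracy over trials 501+).
Estimator checks: 1,000 × 70-trial blocks (study scale) and 350 ×
1,000-trial blocks (asymptotic). F-test calibration: 2,000 simulations.
Selection recovery: exact on noiseless curves, ≥ 80 % over 25 replicates at
noise SD 0.005. Parameter recovery from full staircase cohorts: median ρ
error < 0.05 over 6 single-group replicates of 12 observers. The full
default emulation (60 observers, ~500k trials) runs in a few seconds.
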