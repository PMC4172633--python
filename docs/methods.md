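# Methods

## The two-step contest analysis

The package operationalises the standard framework for inferring
assessment strategies from contest data.  A *dyad* is one contest between
two parties with a known winner, a duration in days (≥ 1), and one or more
nonnegative power measures per side.

**Relative power difference.**  `RPD(p_i, p_j) = (p_i − p_j)/(p_i + p_j)`:
bounded in (−1, 1), antisymmetric, zero at equality, positive when side
*i* is stronger, and unitless so that measures on very different scales
are comparable.  Both powers zero is a domain error.  A log-ratio variant
`log(p_i/p_j)` is available behind a flag for sensitivity analysis; it
shares the sign convention but not the bounds.  The bounded contrast is
the package's fixed default.

**Balanced role assignment.**  Contests are sorted by ascending duration
(ties broken by ascending contest id) and the winner is designated the
focal side at odd 1-based ranks, the opponent at even ranks.  Both the
sort direction and the rank-1 convention are arbitrary; they are fixed so
the assignment is exactly reproducible.  For even N this yields an exact
focal/opponent win balance; `balance_check` additionally reports the mean
durations of contests won by each role and a Welch t comparison on log₁₀
durations as a sanity check.

**Victory screen.**  Per measure: a binomial mixed model of the focal-win
indicator on the (z-standardized) focal-vs-opponent RPD with crossed
random intercepts for focal and opponent identity, compared by a
likelihood-ratio χ²₁ test with the intercept-only model on the same rows.
A measure is an RHP correlate only when its slope is positive *and*
significant; a significant negative slope is reported as anomalous.
Standardization aids optimiser conditioning and leaves the LR statistic
invariant (an affine-rescaling invariance the tests assert); slopes are
reported on both scales.

**Duration pattern.**  Per screened measure, three Gaussian mixed models
of log₁₀ duration — on winner power, loser power and winner-vs-loser RPD,
one predictor per model — with crossed random intercepts for winner and
loser identity.  The one-at-a-time policy follows from the strong mutual
correlations of the three predictors, which `collinearity_report`
quantifies (flag threshold |r| > 0.7).  The absolute-power predictors
enter on the log₁₀ scale by default: capability-type measures are
right-skewed over orders of magnitude, log size is the conventional scale
for RHP proxies, and the verdict logic consumes only slope signs and
significance, which a monotone transform does not distort.  Raw-scale
predictors are available (`log_powers=False`).

**Verdict rules**, applied in fixed order at significance level `alpha`
(default 0.05) and trend level `trend_alpha` (default 0.10, matching the
usual reporting of near-significant trends):

1. winner slope significantly negative *and* loser significantly positive
   → `mutual-or-CAM` (the mutual-assessment signature, which cumulative
   damage can mimic — hence the compound name; the diagnostic never
   claims to prove mutual assessment);
2. both significantly positive → mutual assessment ruled out; the verdict
   is `pure-self-assessment` when the loser's standardized slope is
   strictly larger, else `winner-dominated-attrition`;
3. one significantly positive, the other a positive trend
   (p < `trend_alpha`) → `mutual-ruled-out-attrition`;
4. otherwise `inconclusive`.

The relative-power slope never enters the rules — a negative
duration-vs-RPD association can arise spuriously — and is kept in the
rationale only.  "Stronger association" in rule 2 is operationalised as
the comparison of standardized slopes; this is the one genuinely open
interpretive choice in the framework (verbal treatments compare
significance informally), and it is deliberately a pure, documented
function of the fitted numbers.

## Model estimation

Both families are estimated from scratch; no mixed-model library stands
behind them (statsmodels and quadrature serve only as independent
cross-checks in the tests).

**Binomial GLMM (Laplace).**  Crossed random intercepts are independent
Gaussian factors, one variance each.  For fixed (β, σ) the random-effect
vector is profiled by a penalised Newton iteration (IRLS with
step-halving); the Laplace marginal log-likelihood is
`ℓ = f(b̂) − ½ b̂ᵀD⁻¹b̂ − ½ log|D| − ½ log|ZᵀWZ + D⁻¹|`.  The outer
optimisation is L-BFGS-B over (β, log σ) with log-SD box [−8, 5] — the
lower edge is numerically a zero component, at which the fit reduces to
ordinary logistic regression — from a fixed 3-point start grid
(log σ ∈ {−4, −0.5, 0.7}); everything is deterministic.  Fixed-effect
covariance comes from the Schur complement of the joint (β, b) curvature.
The implementation reproduces lme4's Laplace fits (log-likelihood agreement
to ~1e-5 on shared fixtures, checked during development).  Complete
separation is flagged (saturated fitted probabilities or runaway slopes),
not silently reported.

**Gaussian LMM (REML/ML).**  The profiled form is optimised over the k
log-ratios σ_k/σ_e only: at each candidate point the GLS fixed effects and
the residual variance have closed forms, with
`ℓ_R = −½[(n−p)(log σ̂²_e + log 2π + 1) + log|V₀| + log|XᵀV₀⁻¹X|]`.
Dense Cholesky factorisations are used throughout (designs here are a few
hundred rows).  ML uses the analogous unrestricted profile; LR tests
always compare ML fits, refitting REML models by ML on demand, and retry
from the multi-start grid if a full fit lands below its reduced model
before raising.

**F tests.**  Single-coefficient Wald F with Satterthwaite denominator
degrees of freedom: `df₂ = 2v²/Var(v)` where `v = cᵀ(XᵀV⁻¹X)⁻¹c` and
`Var(v)` comes from the delta method with the inverse REML observed
information (numerical Hessian on the raw variance scale, central
differences clamped away from the zero boundary).  Components at the zero
boundary are held fixed; with no free random components the classical
`n − p` is returned exactly.  Kenward-Roger's additional small-sample
covariance adjustment is not implemented: requests for it fall back to
Satterthwaite with a warning, and every test result records the method
actually used.  The diagnostic consumes slope signs and approximate
p-values, not third-decimal degrees of freedom, so the Satterthwaite
floor is adequate for the verdicts; fractional df are reported as
computed.

## The contest simulator

The generator emulates the structure of interstate-war data: a pool of
states whose identities recur across contests (exercising the crossed
random intercepts), five positive, mutually correlated power measures per
side, and durations in whole days.

Log-RHP decomposes into a persistent state level (SD `rhp_sigma`, default
1.0) plus a between-war, within-state draw (SD `rhp_within_sd`, default
0.6) — national capabilities drift between a state's wars, and without
this within-state variation a state-identity intercept would absorb the
state-level persistence signal entirely, which no real capability data
behave like.  Each measure is `exp(loading · log RHP + noise)` with
per-measure loadings (0.7–1.0; the composite index loads 1.0) and
log-scale measurement noise of SD 0.3, a modest error consistent with
accounting-type capability measures; the composite index is normalised by
the pool total so it behaves like a capability *share* in [0, 1].
Multiplicative scale constants per measure are cosmetic.

Mechanisms (all with multiplicative log-normal duration noise, SD
`noise_sd` = 0.4, and durations rounded up to whole days):

* **WOA**: persistence `T_k = a·R_k^b·ε_k`; the smaller persistence loses
  and sets the duration.  The loser-RHP slope is direct; the winner-RHP
  slope is the selection effect of the min rule (strong winners permit
  strong losers).
* **SAM**: the stronger side wins with probability Φ(|RPD|/s) and
  `duration = a·exp(−|RPD|/s)·ε` — evenly matched opponents take longest;
  `s` (`sampling_error`, default 0.25) is the accuracy of the mutual
  comparison.
* **CAM**: `T_k = a·R_k^b/(1 + d·R_opp)·ε_k` — each side's give-up time is
  eroded by its opponent's strength; `d = 0` recovers WOA draw for draw
  (the same RNG stream feeds both).
* **NULL**: fair-coin winner, power-independent duration — the
  false-positive control.

These equations are the package's own constructions: the theory they
encode specifies assumptions and predicted slope patterns, not functional
forms, and each equation is the simplest form that provably produces its
mechanism's pattern (the large-sample slope tests in the suite verify
this by direct regression on simulated tables).  Defaults were fixed once
so that each mechanism's signature is statistically detectable at the
simulation sizes the validation harness uses (200 contests, 30 states);
they are the package's study conditions, not tuning knobs.  One RNG
stream per dataset is split per contest by counter, so enlarging
`n_contests` extends a table without reshuffling earlier contests.

What the simulator does *not* emulate: assortative pairing of strong
states, coalition contests, capability trends over historical time,
escalation dynamics within a contest, and motivation/resource-value
asymmetries.  Passing recovery tests therefore show that the pipeline
identifies each mechanism from data that *cleanly* embodies it — they do
not show that real war data are clean, and the `mutual-or-CAM` /
rule-out asymmetry of the verdict vocabulary is the honest limit of what
the slope pattern can say.

## Ingestion conventions

Delimited war/participant and state-year capability tables in the v4.0
dialect (column names, numeric outcome codes and −9 sentinels all
configurable).  Filters: exactly two distinct states per war, exactly one
coded winner and one coded loser; stalemates/transformations/other
unclear outcomes, coalitions and inconsistent codings are excluded with
machine-readable reasons, and dyads plus exclusions always partition the
input wars.  Duration is the inclusive day count ((end − start) + 1, so a
one-day war is 1); war start/end are the earliest entry/latest exit over
participants; a state with several entry dates uses the earliest entry
year; the "transformed" exit is applied per war.  Each side carries the
capabilities of its year of entry.  Missing capabilities default to
per-measure exclusion downstream ("drop the dyad from analyses of the
affected measure only"); a strict drop-the-dyad policy is selectable.
Sentinel values are normalised to explicit NaN at the reader, never left
negative.  Floats are parsed with round-trip precision so simulator-
emitted files re-ingest bit-exactly.

## Validation harness and problem sizes

The recovery experiment replicates simulate → two-step → verdict, keyed
on the composite-index measure (the primary measure of the analysis),
with all five measures screened per replicate.  Validation defaults: 100
replicates per mechanism at 200 contests each, single-start optimiser
control (the multi-start grid changes no verdict in these well-conditioned
designs and triples the cost).  Thresholds: WOA replicates in the
self-assessment family ≥ 90% with ≤ 2% mutual-or-CAM; SAM mutual-or-CAM
≥ 90%; NULL inconclusive-or-unscreened ≥ 85%, with per-measure screen
pass rates near the nominal α.  Calibration checks use 500 null
replicates at 44 contests (the scale of the real dataset the framework
targets) for the LR screen's type-I error and 100 replicates at n = 200
for Gaussian slope recovery.

## Numerical choices and known limitations

* Variance components live on the log-SD scale with box [−8, 5]; the
  lower edge is reported as a boundary fit.  Gradient tolerance 1e-6
  (binomial) / 1e-8 (gaussian); all controls overridable per fit.
* Ties in the duration sort, zero-power sides (RPD undefined), constant
  predictors (unstandardizable) and empty inputs raise explicit errors or
  are reported — never silently imputed.
* Laplace accuracy: on small binary clusters with large fitted
  random-effect SDs the Laplace optimum can sit visibly below the exact
  marginal likelihood; this is a property of the approximation (shared by
  the standard implementations), not of this implementation, and the
  tests bound it explicitly.
* The Satterthwaite Hessian is numerical; in near-degenerate fits df₂ is
  clamped to [1, n − p].
* Multi-membership random effects (one shared per-country variance across
  the focal and opponent roles) are noted as an alternative to the
  two-factor crossed structure but not implemented; with the crossed
  default a state appearing in both roles contributes to both factors.
* Random slopes, non-nested model comparison, and families beyond
  binomial/gaussian are out of scope.
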