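# contestkit

Assessment-strategy analysis of dyadic contests — animal fights or
interstate wars — built around the two questions contest theory asks of
any fight: *which traits actually confer Resource Holding Power (RHP)?*
and *how does RHP shape contest duration?*  The answer to the second
question discriminates between the ways a loser can reach its giving-up
decision:

* **self-assessment** (war-of-attrition family): each side persists to its
  own cost threshold, so duration rises with *both* sides' RHP, most
  strongly the loser's;
* **mutual assessment** (sequential-assessment family): the weaker side
  quits once it knows it is weaker, so duration rises with loser RHP but
  *falls* with winner RHP;
* **cumulative assessment (CAM)**: self-thresholds plus opponent-inflicted
  damage — which mimics the mutual-assessment slope signature without any
  information exchange, so that signature can never *prove* mutual
  assessment, while two positive slopes can *rule it out*.

## The statistical framework

Stage 1 — **victory screen**.  Contests are listed by duration and the
winner is alternately labelled *focal* or *opponent*, so focal status
carries no information about winning (exactly balanced wins for even N).
For each candidate power measure `P` the signed relative power difference

    RPD = (P_focal − P_opponent) / (P_focal + P_opponent)   ∈ (−1, 1)

predicts victory in a mixed-effects logistic regression (Laplace maximum
likelihood) with crossed random intercepts for focal and opponent
identity; a likelihood-ratio χ² test against the intercept-only model
screens the measure.  Only significantly *positive* slopes qualify a
measure as an RHP correlate.

Stage 2 — **duration pattern**.  For each screened measure, three Gaussian
mixed models of log₁₀ duration — on winner power, loser power and
winner-vs-loser RPD, one predictor per model because the three are
collinear — are fitted by REML with crossed random intercepts for winner
and loser identity; fixed effects are tested with F statistics using
Satterthwaite denominator degrees of freedom.  The sign/significance
pattern of the winner and loser slopes is mapped to a verdict:
`mutual-or-CAM`, `pure-self-assessment`, `winner-dominated-attrition`,
`mutual-ruled-out-attrition` or `inconclusive`.  The relative-power slope
is reported but never drives the verdict (it can arise spuriously).

Both model families are implemented from scratch as scikit-learn-style
estimators (`BinomialGLMM`, `GaussianLMM`) and are exercised against
independent oracles (adaptive Gauss–Hermite quadrature, classical ANOVA
moments, statsmodels, and simulation) in the test suite.

The package also ships

* readers for the inter-state war and national-material-capabilities
  tables of the Correlates of War project (v4.0 dialect; column names,
  outcome codes and sentinels configurable), with the exclusion filters
  that reduce a war file to two-state wars with a clear winner and loser,
  duration in days, and per-side capabilities at the year of entry;
* a seeded generative simulator of dyadic contests under the
  war-of-attrition (WOA), sequential-assessment (SAM), cumulative-
  assessment (CAM) and null mechanisms, with COW-dialect file emission, so
  every stage of the pipeline is testable without the external data.

## Worked example

```python
from contestkit import SimulationConfig, simulate_dataset, run_two_step

cfg = SimulationConfig(mode="WOA", n_contests=200, seed=42)
dyads, _ = simulate_dataset(cfg)
report = run_two_step(dyads, measures=("cinc", "milper"))
```

Printing the screen and the duration pattern:

```text
cinc: victory slope +4.77, LR chi2(1) = 140.7, p = 1.9e-32, RHP correlate: True
milper: victory slope +4.43, LR chi2(1) = 126.1, p = 3e-29, RHP correlate: True
cinc winner   slope +0.129 (std), F(1,77.8) = 26.46, p = 1.96e-06
cinc loser    slope +0.474 (std), F(1,57.7) = 1133.85, p = 1.27e-39
cinc relative slope -0.180 (std), F(1,193.8) = 44.56, p = 2.53e-10
cinc verdict: pure-self-assessment
milper winner   slope +0.128 (std), F(1,79.4) = 27.37, p = 1.33e-06
milper loser    slope +0.475 (std), F(1,61.9) = 950.14, p = 2.91e-39
milper verdict: pure-self-assessment
```

Reading the output: both measures pass the victory screen (strongly
positive RPD slopes), so both are genuine RHP correlates in this
simulation.  Duration rises with the power of winners *and* losers, the
loser's standardized slope dominating — exactly the attrition signature
the WOA generator encodes — so mutual assessment is ruled out and the
verdict is `pure-self-assessment`.  The negative relative-power slope
(shorter wars between mismatched sides) is recorded but, on its own,
would have been uninformative.

The same analysis is available from the shell:

```sh
contestkit simulate --config config.yaml --emit-cow   # synthetic dataset
contestkit prepare  --config config.yaml              # ingest + dyads + assignment
contestkit analyze  --config config.yaml              # two-step report
contestkit validate --config config.yaml              # mechanism-recovery check
```

where `config.yaml` names either a simulator block or a real
war/capability file pair, e.g.

```yaml
war_file: Inter-StateWarData_v4.0.csv
capabilities_file: NMC_v4_0.csv
measures: [pec, milper, tpop, upop, cinc]
alpha: 0.05
trend_alpha: 0.10
output_dir: run
```

The Correlates of War files themselves are distributed at
correlatesofwar.org and are never downloaded by the package.

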