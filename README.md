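# dyadkit

Dyadic data analysis for **distinguishable dyads** — couples, caregiver/patient
pairs, parent/child pairs — where the two members' scores are statistically
nonindependent and that nonindependence is the phenomenon of interest, not a
nuisance.

`dyadkit` fits the three classical covariance-structure models for one
predictor *X* and one outcome *Y* measured on both members of each dyad:

- **APIM** (actor–partner interdependence model): each member's outcome is
  regressed on both members' predictors,

  *Y₁ = a₁X₁ + p₂₁X₂ + e₁,  Y₂ = a₂X₂ + p₁₂X₁ + e₂*,

  with actor effects *a₁, a₂*, partner effects *p₁₂, p₂₁*, a free X–X
  covariance (partner similarity on the predictor) and a free residual Y–Y
  covariance (unexplained nonindependence). The basic model is saturated.
- **MIM** (mutual influence model): no partner-X paths; instead the two
  outcomes influence each other directly (*Y₁ ⇄ Y₂*), a nonrecursive
  feedback loop identified by each member's own predictor. Each X reaches
  the partner's outcome only indirectly, through the member's own outcome.
- **CFM** (common fate model): couple-level latent variables, each measured
  by the two members' scores with loadings fixed to 1, carry the X → Y
  effect at the dyad level; within-person residual covariances absorb the
  individual-level association.

All three are estimated by maximum-likelihood covariance-structure analysis
in RAM form, Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, minimizing
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p, with χ² = n·F_ML(θ̂), normal-theory
standard errors, fit indices (χ²/df, CFI, TLI, RMSEA, SRMR), equality
constraints by parameter-label sharing, and χ²-difference tests for nested
models. Because only second moments enter the likelihood, every model can
be fitted **directly from published summary statistics** (n, means, SDs,
correlations) — no raw data required.

The package also includes questionnaire scoring (sum scores with
reverse-coding, Cronbach's α), paired t tests reconstructed from summary
moments, a seeded multivariate-normal dyad simulator with known
APIM/MIM/CFM structure, and Monte Carlo parameter-recovery experiments.

## Worked example

The packaged example dataset is the printed summary table of a
cross-sectional study of 141 infertile couples: anxiety (7-item hospital
anxiety subscale, range 0–21) and marital satisfaction (10-item scale,
range 10–50) for both spouses.

```python
import dyadkit as dk

moments = dk.load_couples_moments()          # n=141, means, SDs, correlations
design  = dk.DyadDesign(roles=("man", "woman"),
                        predictor="anxiety", outcome="satisfaction")
S = design.covariance(moments)               # reconstructed 4x4 covariance

fit = dk.fit_ml(dk.build_apim(design), S, moments.n)
print(fit.table())
```

```
Model: APIM[basic]  (n = 141)
parameter                           estimate        SE       z       p
actor:man                             -0.458     0.122   -3.76   0.000
partner:woman->man                    -0.253     0.117   -2.16   0.031
partner:man->woman                    -0.151     0.127   -1.20   0.232
actor:woman                           -0.444     0.122   -3.64   0.000
var:anxiety_man                       18.359     2.187    8.40   0.000
cov:anxiety_man~anxiety_woman          3.980     1.638    2.43   0.015
var:anxiety_woman                     19.751     2.352    8.40   0.000
resvar:satisfaction_man               36.691     4.370    8.40   0.000
rescov:satisfaction_man~satisfaction_woman    14.002     3.424    4.09   0.000
resvar:satisfaction_woman             39.718     4.730    8.40   0.000
chi2 = 0.000, df = 0, p = -, CFI = 1.000, TLI = 1.000, RMSEA = 0.000, SRMR = 0.000
```

Each 1-point rise in a man's anxiety predicts a 0.46-point drop in his own
marital satisfaction (actor effect) and a 0.15-point (nonsignificant) drop
in his wife's (partner effect); a wife's anxiety predicts both her own
(−0.44) and her husband's (−0.25) satisfaction. The saturated model has
χ² = 0 by construction. Testing whether the two actor effects differ by
gender:

```python
constrained = dk.fit_ml(dk.build_apim(design, "actor_equal"), S, moments.n)
cmp = dk.chisq_diff_test(constrained, fit)
# actor-equality test: dchi2(1) = 0.006, p = 0.940  -> no gender difference
```

`dk.build_mim` / `dk.mim_indirect_effects` and `dk.build_cfm` /
`dk.cfm_latent_r2` work the same way; `dk.run_hypothesis_suite(moments,
design)` runs the standard seven-hypothesis battery (actor, partner,
feedback and couple-level effects, plus their gender-equality tests) in one
call.

### Command line

```sh
dyadkit summarize config.yaml          # descriptives + paired comparisons
dyadkit fit config.yaml --out-dir out  # one column per model variant
dyadkit simulate config.yaml           # seeded synthetic dyads + truth file
dyadkit hypotheses config.yaml
```

Configs are plain YAML (`mode: raw` with a column mapping, or
`mode: moments` with a moments JSON); every human-readable report has a
full-precision JSON sidecar.

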