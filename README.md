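# riskcart

Weighted classification-tree discovery of early-life subgroups at high risk
of a binary adolescent outcome, with prevalence-ratio risk stratification,
cross-cohort validation and screening diagnostics.

## The problem

Epidemiological cohorts of children carry dozens of dichotomized early-life
risk and protective factors (family adversity, parenting style, prenatal
exposures, socioeconomic conditions, ...) measured years before an outcome
such as adolescent suicidal thoughts. Individual factors predict poorly;
risk concentrates in *conjunctions* of factors — subgroups of children who
share a constellation of stressors. `riskcart` implements the tree-based
procedure for finding those subgroups in weighted survey data and for
checking whether the resulting classification rule travels to a second
cohort measured with different instruments.

The pipeline:

1. **Grow** the maximal binary classification tree. Each node holds a
   survey-weighted outcome prevalence p̂ = Σᵢ wᵢyᵢ / Σᵢ wᵢ; splits maximise
   the weighted Gini decrease ΔG = G(parent) − Σ_c (W_c/W) G(c) with
   G = 2p̂(1−p̂), over candidate splits x_j = 1 ("yes") vs x_j = 0
   ("no/missing"). A split is admissible only if both children contain at
   least `n_min` *unweighted* individuals (by convention 1% of the sample);
   growth stops when no admissible split remains.
2. **Designate risk** per node against the cohort base rate π₀ (the root's
   weighted prevalence): *high* if p̂ > 2π₀, *low* if p̂ < π₀/2, otherwise
   *moderate* (boundaries are strict).
3. **Prune for risk homogeneity**: bottom-up, any subtree whose nodes all
   share one risk level adds no differentiation in risk and is collapsed to
   its parent node, which keeps its pooled counts and prevalence.
4. **Extract profiles**: each remaining high-risk leaf becomes a subgroup
   profile — the conjunction of yes/no conditions on its root-to-leaf path.
5. **Validate externally**: profiles are ported to a second cohort through
   a closest-proxy predictor mapping (conditions on variables with no
   substitute are dropped or disable the profile, per policy) and the rule
   is re-evaluated there.
6. **Evaluate**: the high-risk-vs-not rule is scored against the primary
   outcome and six secondary adolescent outcomes (antisocial behaviour,
   substance misuse, poor physical health, poor mental health, risky health
   behaviours, poor academic performance) by sensitivity, specificity, PPV
   and NPV with 95% intervals, and benchmarked against a stepwise-selected
   weighted logistic regression dichotomized at a probability threshold.

Because the real cohorts behind such analyses are restricted-access
microdata, the package ships a synthetic-cohort generator
(`riskcart.simulate`) that emulates their statistical structure — correlated
binary predictors via a shared latent adversity factor, missingness folded
into the "no/missing" level, gamma survey weights, a calibrated ~12%
weighted base prevalence, correlated secondary outcomes, and planted
high-risk subgroups — so the entire pipeline is testable end-to-end.

## Worked example

```python
from riskcart import (CohortSpec, PlantedSubgroup, generate_cohort,
                      HighRiskTreeModel)

groups = (
    PlantedSubgroup(((70, "yes"), (72, "yes"), (74, "yes")), 0.41),
    PlantedSubgroup(((70, "no"), (60, "yes"), (65, "yes")), 0.33),
)
spec = CohortSpec(n_individuals=6388, planted_subgroups=groups, seed=1)
cohort = generate_cohort(spec)

result = HighRiskTreeModel(cohort, n_min=64).fit()
print(result.summary())
```

```
High-risk subgroup discovery (weighted classification tree)
==============================================================
n (unweighted):        6388
outcome:               y_primary
n_min per child node:  64
base rate (weighted):  11.5%
high / low cut-offs:   >23.0% / <5.8%
maximal tree leaves:   69
pruned tree leaves:    46 (high 5, moderate 21, low 20)

High-risk subgroup profiles
--------------------------------------------------------------
subgroup_1: 43.9%, n = 635
    - x0075 = yes
    - x0073 = yes
    - x0071 = yes
...
```

The base rate is the weighted prevalence of the outcome in the whole
cohort (11.5% here), so leaves above 23.0% are high risk and below 5.8%
low risk. `subgroup_1` recovers the first planted conjunction exactly
(predictors 71, 73, 75 in 1-based naming): 43.9% of its 635 members carry
the outcome, almost four times the base rate. Screening performance of the
rule "member of any high-risk subgroup":

```python
d = result.diagnostics()
print(f"sensitivity {d.sensitivity.as_percent()}  specificity {d.specificity.as_percent()}")
# sensitivity 58.9 (55.4,62.4)  specificity 88.4 (87.5,89.2)
```

i.e. the rule catches 58.9% of the children who later report the outcome
while flagging few of those who do not. The same `result` object ports the
profiles to a validation cohort (`result.port(mapping)`), applies them
(`result.classify(cohort2)`), and scores all seven outcomes
(`result.evaluate_outcomes()`); `StepwiseLogisticModel(cohort).fit()` gives
the logistic comparator.

A command-line pipeline mirrors the library:

```bash
riskcart simulate --spec spec.yaml --seed 1 --out cohort.csv
riskcart grow     --cohort cohort.csv --nmin 64 --out tree.json
riskcart prune    --tree tree.json --out pruned.json
riskcart profile  --tree pruned.json --out profiles.json
riskcart evaluate --profiles profiles.json --cohort cohort.csv --out metrics.json
riskcart baseline --cohort cohort.csv --out logistic.json
```

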