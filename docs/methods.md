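# Methods

## The discovery procedure

`riskcart` fits a binary classification tree to a weighted cohort and turns
it into a small set of interpretable high-risk subgroup profiles.

**Growth.** Predictors are binary, coded 1 = yes and 0 = no/missing: item
non-response is folded into the reference level before modelling, so the
tree needs no surrogate splits or per-node missingness handling. A node is
split on the predictor that maximises the decrease in weighted Gini
impurity, ΔG = G(parent) − (W₁/W)·G(yes child) − (W₀/W)·G(no child) with
G = 2p̂(1−p̂) and p̂ the survey-weighted prevalence. Gini is the
conventional classification criterion of recursive-partitioning software
and is what this package adopts; survey weights enter impurity and
prevalence, while the minimum-node-size rule counts *unweighted*
individuals, because the rule is stated as a head count. A split is
admissible when both children hold at least `n_min` individuals and
ΔG strictly exceeds `min_impurity_decrease` (default 0: the tree is grown
truly maximal under the node-size rule, which is the only stopping rule).
Ties in ΔG break to the lowest predictor index in the declared column
order; node ids are assigned in depth-first, yes-branch-first visit order.
Both choices exist purely to make growth deterministic.

**Risk designation.** Every node is labelled against the base rate π₀,
defined as the weighted prevalence at the root of the analysis cohort:
high if p̂ > 2π₀, low if p̂ < π₀/2, moderate otherwise. The inequalities
are strict — a node exactly at a cut-off is moderate. Designation uses
the weighted node prevalence by default; the unweighted prevalence is also
stored on every node for sensitivity analyses.

**Pruning.** Post-order, any internal node whose entire subtree — the node
itself, internal descendants and leaves alike — shares one risk level is
collapsed into a terminal: the splits below it never changed the risk
designation, so they add no stratification. The collapsed node keeps its
own pooled counts and prevalence (already the weighted pool of its former
leaves), so outcome and weight totals are conserved exactly. Requiring the
*whole* subtree to share the level (not just the leaves) is deliberate:
a moderate node whose leaves are all high still marks a real change in
designation along the path. Bottom-up collapse is idempotent and reaches
the minimum attainable number of terminals among all sequences of
homogeneous-subtree collapses (verified exhaustively on all small tree
shapes in the test suite).

**Profiles, classification, validation.** Each high-risk leaf yields a
profile: its root-to-leaf conditions, training prevalence and unweighted n,
ordered by descending prevalence. An individual is classified high-risk iff
they satisfy every condition of at least one profile; on the training
cohort this is exactly leaf membership, and `matched_profile_id` records
the first satisfied profile in stored order (profiles from disjoint leaves
cannot overlap on the training cohort, but ported or noisy cohorts can
create overlaps, so a deterministic first-match rule is fixed). For
external validation, profiles pass through a closest-proxy predictor
mapping. A condition on a variable with no proxy follows one of three
policies: `profile-never-fires` (default — never call someone high-risk on
a condition that cannot be verified), `drop-condition` (closest-proxy
semantics; monotonically widens the profile's match set), or `fail`. No
tree is re-grown and no threshold recalibrated on the validation cohort:
the discovery rule is ported as-is.

**Diagnostics.** The high-risk rule against any binary outcome is a 2×2
table kept in weighted and unweighted form. Point estimates (sensitivity,
specificity, PPV, NPV) use the weighted cells; 95% intervals are Wald
proportion intervals around the weighted estimate with the relevant
margin's *unweighted* head count as n, truncated to [0, 1] (Wilson is
available as an option). Survey-design variance estimation (replicate
weights, design effects) is out of scope; with informative weights the
intervals are approximate. A metric whose margin is empty is reported as
undefined with an explicit flag, never silently as zero. Percentages print
to one decimal.

**Logistic comparator.** A weighted logistic regression fitted by IRLS
(via statsmodels GLM with variance weights), with classical stepwise
selection: enter the candidate with the smallest Wald p below
`entry_alpha` (default 0.05), then remove included terms with p above
`stay_alpha` (default 0.05); revisiting a previously seen model state
terminates the loop, which guarantees termination without limiting the
search. Wald p-values drive both directions — the simplest consistent
criterion. The fitted model is dichotomized at a probability threshold
(default 0.5; a sweep utility reports the sensitivity/specificity curve)
and scored with the same diagnostics, so the tree rule and the regression
are compared on identical footing. At a ~12% outcome prevalence the 0.5
threshold yields the characteristic pattern: very high specificity, very
low sensitivity. Separation and non-convergence raise explicit errors.

## The synthetic cohort generator

Real cohorts of this kind are restricted-access, so the generator
(`riskcart.simulate`) emulates their statistical structure; it defines the
conditions under which the pipeline is exercised and tested.

- **Predictors.** p = 75 binary variables. Co-occurrence of adversities is
  induced by one shared latent factor zᵢ ~ N(0,1):
  predictor j is "yes" when √ρ·zᵢ + √(1−ρ)·εᵢⱼ falls below the quantile of
  its marginal rate. ρ = `clustering_strength` (default 0.2, a modest
  latent correlation consistent with the well-documented clustering of
  early-life stressors). Default marginal yes-rates spread evenly from 10%
  to 50% across predictors, spanning rare exposures to common ones.
  Missingness (default rate 0.15 per predictor) is generated and
  immediately folded to 0, matching the no/missing coding; raw three-level
  yes/no/missing tables are accepted only as an input dialect via
  `encode_predictors`.
- **Weights.** Gamma-distributed with mean 1 and coefficient of variation
  `weight_dispersion` (default 0.5) — non-negative and right-skewed like
  post-stratification survey weights, with mean 1 so weighted and
  unweighted n stay comparable. Dispersion 0 gives unit weights.
- **Primary outcome.** Planted subgroups are conjunctions of 1–9 predictor
  conditions with a configured outcome prevalence (25–41% in the shipped
  study conditions, against a 12% base). Membership is resolved on the
  observed predictors, first matching subgroup wins in declared order.
  Non-members draw the outcome at a background rate solved from the
  realized weighted membership shares so the overall weighted prevalence
  approaches `base_prevalence` (default 0.12); if no rate in [0, 1] can
  achieve this, a `CalibrationError` is raised rather than silently
  mis-calibrating.
- **Secondary outcomes.** Six, with default overall prevalences (15.0,
  26.4, 14.0, 16.0, 11.4, 18.0)% — the range endpoints anchor the emulated
  11.4–26.4% span, the other four sit inside it. Subgroup members draw each
  at twice its target prevalence (capped at 0.95), non-members at a
  background rate calibrated to the overall target. This one-parameter
  lift reproduces multifinality — the same planted conjunctions predict
  all seven outcomes — without asserting any particular cross-outcome
  correlation structure.
- **Validation cohort.** Generated from the same structural spec (so
  planted subgroups exist on the latent, pre-noise variables), then each
  mapped predictor is flipped independently with its mapping entry's
  flip probability and renamed to the proxy name; unmapped variables are
  dropped and reported. Flip probability 0.5 renders a proxy independent
  of the latent variable, the degradation end-point used in tests.

What the generator does *not* emulate: longitudinal wave structure,
informative attrition, item-level questionnaire content, design-based
weight construction, and realistic block-correlation among predictors
beyond the single shared factor. Tests passing on these cohorts show the
*procedure* is correct (growth, designation, pruning, porting, scoring),
not that any particular substantive finding would replicate in real data.

## Problem sizes and numerical choices

The shipped study conditions use a discovery cohort of n = 6,388 with
n_min = 64 (1% of the sample) and a validation cohort of n = 4,700; the
profile-recovery study uses n = 20,000 so planted cells of a few percent
comfortably clear the 1% minimum node size. Tree growth is vectorized
across predictors, so these runs take seconds. Impurity comparisons use
exact floating arithmetic with ties broken by column order; collapsed-node
prevalences are recomputed from weighted totals, never averaged from child
prevalences, preserving the conservation invariant to rounding error.
Degenerate splits (an empty side) score a decrease of 0 and are never
chosen. The recovery criterion — mean Jaccard overlap ≥ 0.6 between
recovered and planted condition sets — was fixed before testing.

## Known limitations

- Greedy growth with a single-factor correlation structure can substitute
  a correlated proxy for a planted defining predictor, or append an extra
  noise condition that survives pruning; recovery is therefore measured by
  Jaccard overlap, not exact set equality.
- Confidence intervals ignore the survey design (see above) and the
  logistic comparator's threshold choice is conventional, not optimised.
- The pruning rule stratifies by *designation*, not by statistical
  significance: two leaves at 25% and 41% are both simply "high".
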