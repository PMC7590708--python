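# Methods

## Model

All analyses concern the five-component frailty phenotype measured on
continuous scales: exhaustion (SF-36 vitality, 0–100), physical activity
(PASE score), grip strength (vigorimeter units), gait speed (cm/s) and
unintentional weight loss. The factor mixture model couples a latent class
variable (K classes, mixing π) with a one-dimensional severity factor:

    y_ic = I_kc + F_kc · η_i + e_ic,   η_i | k ~ N(α_k, ψ_k),   e_ic ~ N(0, θ_kc).

Two items depart from the Gaussian law. Gait speed is left-censored at a
known floor (subjects unable to perform the walk test): a censored cell
contributes Φ((floor − μ)/σ) — a Tobit term. Weight loss is two-part: a
Bernoulli occurrence with a *class-specific* logit threshold and no factor
loading, plus a Gaussian magnitude in kg among losers that does load on the
factor; the magnitude cell is simply missing when no loss occurred. The
occurrence thresholds stay class-specific in every family — with no factor
loading on that item, class variation in occurrence can only enter through
the thresholds, and freezing them would make the strong-invariance null
unable to represent any weight-loss gradient at all.

Invariance templates define the family. `LCA` drops the factor entirely
(latent profile analysis on continuous items). `SiMI`/`SoMI` fix intercepts
and loadings across classes — classes then differ only through α_k, i.e.
they are a categorical rendering of one continuum; SiMI additionally pools
residual and factor variances (it is the `ev` member of that branch, and
`SiMI-uv` is rejected as an illegal spec). `WMI` frees the intercepts,
`NMI` additionally the loadings. Identification: the exhaustion loading is
fixed at 1 (per class under NMI); under SiMI/SoMI one class's factor mean is
fixed at 0 and under WMI/NMI all are (absorbed by the class intercepts); the
occurrence logit follows the intercept block. With K > 1, SiMI/SoMI are the
categorical-approximation null, LCA/WMI/NMI the heterogeneity alternatives;
every K = 1 model is the one-class null.

Parameter counts follow these identification rules (e.g. the 4-class SoMI-uv
on the six-cell item block has 40 free parameters). Software that
parameterizes censored/two-part items differently will print different
totals for the same model; counts here are internally consistent with the
BIC and the chi-square degrees of freedom used everywhere else (binary
5-item LCA: 6K − 1 parameters, GOF df = 31 − (6K − 1) = 26/20/14 for
K = 1/2/3).

## Estimation

EM with the pair (class, quadrature node) as the missing datum: the factor
integral is replaced by a fixed 21-point Gauss–Hermite grid on the
standardized scale (η = α_k + √ψ_k·z), which makes the objective an exact
finite mixture and every conditional-maximization update closed-form —
weighted least squares for intercept/loading blocks (pooled across classes
for invariant blocks, each class weighted by its inverse residual variance),
moment updates for variances, a weighted 2-point regression on the node
locations for (α_k, √ψ_k), truncated-normal moment imputation for censored
cells. The quadrature log-likelihood is monotone non-decreasing across
iterations by construction; the property suite asserts it on every fit.
Class-free models use a single trivial node, collapsing to the standard
diagonal-mixture EM.

For conditionally Gaussian item sets (including censored cells and the
two-part magnitude) the exact marginal likelihood is also available in
closed form: per missing pattern, a rank-one multivariate normal
(Σ = ψ λλᵀ + Θ via Sherman–Morrison) times the conditional normal left tail
for the censored coordinate. This analytic path is the default for
`loglikelihood()` and serves as the independent oracle against adaptive
numerical integration (agreement ≈ 1e-7 on test instances); the 21-node
grid agrees with brute force to ~1e-8 on well-scaled instances and to ~1e-3
per thousand subjects on raw-scale cohort data, which is far below the BIC
differences the selection stage consumes and is, importantly, the *same*
objective for every model being compared.

Starts: perturbed k-means initializations with distance-weighted seeding
(class assignments on standardized, floor-imputed, well-observed columns
plus the occurrence indicator; factor blocks from the pooled within-class
covariance), 50 by default, plus an optional warm start that is first
projected into the spec's constraint set; class-count searches in the
pipeline additionally seed the K-class fit with a split of the
(K − 1)-class solution. Iterations interleave safeguarded SQUAREM
extrapolation (a secant jump through two EM steps, accepted only when it
improves the objective, with step-length growth), which preserves the
monotone trace while converging several-fold faster on the flat ridges
typical of continuum mixtures. Convergence: |Δ log L| < 1e-7, at most 2000
iterations (reduced profiles below). Degeneracy: a
solution whose smallest expected class count falls below 5 is discarded and
flagged — mirroring stopped searches on one-subject classes; if every start
degenerates the fit is returned flagged and unconverged. After fitting,
classes are sorted frail-first by the model-implied anchor mean, and the
factor mean is re-anchored to 0 in the frailest class — the convention the
class tables use.

Entropy is the relative form 1 − Σᵢₖ(−p_ik ln p_ik)/(n ln K) ∈ [0, 1]
(undefined at K = 1). Standard errors come from the central-difference
Hessian of the log-likelihood at the optimum. The bootstrap LRT simulates B
datasets from the fitted null and refits both models per replicate
(warm-started, 1–10 extra starts; a documented tractability reduction
relative to the observed fits), with p = (1 + #{LRT_b ≥ LRT_obs})/(B + 1);
replicates are dropped only on numerical failure (degeneracy-flagged refits
keep their best likelihood, exactly as the observed fits do). An optional
early-stopping rule abandons the loop once rejection at the chosen α is
impossible; the accept/reject decision is unchanged, only the upper tail of
the null distribution goes unexplored.

## The synthetic cohort

The generator draws class-first, then the factor, then components, and is
the study-conditions definition for every simulation:

* loadings (1.00, 4.10, 1.21, 2.17, −0.35), invariant intercepts
  (43.15, 0.00, 34.77, 44.28; kg intercept 7.05), class factor means
  (0, 8.5, 21.7, 32.2) frail→robust, shares (2.7, 25.1, 53.4, 18.8)% — the
  published four-class strong-invariance solution;
* class-specific weight-loss occurrence (38.6, 21.8, 9.5, 3.2)% and
  magnitude means (12.1, 4.4, 3.9, 4.2) kg; the magnitude is drawn
  log-normal (kg is positive; the fitted Gaussian magnitude matches it in
  mean structure, a deliberate generator/fitter decoupling);
* residual variances per class (θ ≈ 100–130 for vitality, 850–1100 for
  PASE, 110–150 for grip, 140–250 for gait, 9 for kg) and factor variances
  (80, 55, 45, 35): not printed anywhere, chosen once so that marginal SDs,
  the ≈20% quintile deficits, and a handful of censored gait tests per 1643
  subjects come out realistic;
* gait floor 15 cm/s (≈ 0.3–0.7% of subjects at the floor);
* sex ~ Bernoulli(0.5) with additive male shifts (+8 PASE, +16 grip,
  +4 gait) and sex-specific heights (155.81/169.55 cm) — structure for the
  stratified cut-point machinery, mild misspecification for the FMM (which
  ignores sex). The one-class fixture sets these shifts to zero: an
  additive sex shift on a component is itself a two-group mixture, which
  would contradict the homogeneity that configuration represents;
* covariates (age, education, self-rated health, chronic diseases,
  cognition, depression, IADL/ADL disability, 3-year mortality) drawn
  conditionally independent of the components given class, with monotone
  class profiles taken from the published class table.

What the generator does *not* emulate: longitudinal attrition, sampling
weights, floor/ceiling truncation of bounded scales (vitality can exceed
100), missing data, and any within-class dependence of covariates on
components. Passing tests therefore demonstrate the estimator and decision
machinery under the assumed generative structure, not robustness to survey
realities.

Default seed 20101; every cohort, fit, bootstrap and study seed derives
from an explicit integer.

## Decision pipeline

Steps: (1) stratified cut points → dichotomization → Fried index → binary
LCA ladder with GOF; (2) one- versus two-factor comparison at K = 1,
EFA-style (factor covariance = I, echelon zero; the two-factor model frees
the muscle-strength pair {gait, grip} from the {exhaustion, activity,
weight-loss} axis; df = 4); (3) K = 1 vs K = 2 per family (BIC + BLRT);
(4) minimal acceptable K: increase K while the BLRT rejects K − 1 and no
degeneracy flag is raised; (5) ev vs uv at the selected counts (BLRT);
(6) ordering of class-specific classification parameters across components
(direction-aligned dense ranks, ties collapsed at 1e-6; models whose
components induce more than one ranking are excluded — two orderings means
two putative syndromes); (7) surviving heterogeneity models against the
strong-invariance winner — non-nested, decided by BIC; (8) class profiles
on components and covariates for the final model and the Fried index.

Verdict: `syndromic` if a surviving single-gradient heterogeneity model
beats the null by BIC; otherwise `categorical-approximation-of-continuum`
if some factor family rejected K = 1; otherwise `homogeneous`. The
one-class judgment deliberately excludes the profile families: a
class-free profile model rejects K = 1 against *any* continuous gradient
(its one-class null has a diagonal covariance), so its rejection carries no
evidence of true classes — profile models still get their full shot at the
verdict through the step-7 BIC comparison. Significance level α = 0.05
throughout, configurable.

## Problem sizes and reduced profiles

The default configuration (50 starts, B = 1000, 21 nodes, all eight family
variants) reflects the analysis a user would run once on a real cohort. The
test and reproducibility studies use reduced profiles, chosen as package
defaults for simulation studies: `PipelineConfig.fast_profile` (B = 19 with
decision-exact early stopping, K ≤ 3, 2 starts, 11 nodes, 400/200 iteration
caps, and the five verdict-relevant family variants — the equal-variance
members of the heterogeneity families compete only in step 5 and are
dominated on unequal-variance data); pipeline self-consistency at n = 1100
(four-class continuum), n = 500 (profile classes) and n = 300 (one-class)
over 10 seeds per scenario; parameter recovery on 20 item matrices of
n = 1643; BLRT calibration with B = 99 over 200 one-class datasets of
n = 300. Recovery of the invariant intercepts is
assessed in the mean-centered parameterization I* = I + F·Σπ_kα_k: the raw
intercepts are anchored at the 2.7% frail class, so their estimates inherit
that tiny class's location noise even at the true optimum, whereas I* is
anchor-free and estimates the marginal item locations.

## Known limitations

* One factor only in the mixture models (the two-factor model exists solely
  in the step-2 CFA); the occurrence item cannot load on the factor.
* At most one censored cell per row in the analytic marginal (gait is the
  only censored item here).
* The fixed-grid quadrature loses absolute accuracy when the factor
  posterior is very concentrated relative to the prior (large ψ·Σλ²/θ);
  model comparisons are unaffected because all models share the objective,
  and the analytic path is exact for the default item set.
* Class shares and class-specific variance parameters of
  strong-invariance models are weakly identified by construction (the model
  is a continuum being sliced); only their invariant structure, loadings
  and the gradient ordering are treated as substantively interpretable.
* The Poisson-with-offset magnitude item model is not implemented; the
  two-part Gaussian-magnitude representation is used throughout.
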