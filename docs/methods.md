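# Methods

This note documents the statistical content of `otiskit`: the generative
model behind the synthetic cohorts, the estimators, the numerical choices,
and what the package's tests do and do not establish about real data.

## 1. The generative model

### Structural layer

The cohort generator realizes a recursive linear system over standardized
variables (mean 0, variance 1). Writing `z(·)` for the standardized version
of a quantity, the default ("paper") preset generates, per infant × plasma
visit (12 and 18 mo):

```
ln BCAA    = 0.45·z(recent protein) + e          (plus a direct diet-arm shift, §3)
ln IGF-1   = 0.40·z(protein AUC) + 0.16·z(ln BCAA) + e
ln Ins/Glu = 0.15·z(ln BCAA) + e
weight     = 0.36·z(protein AUC) + 0.13·z(ln Ins/Glu) + 0.39·z(birth weight)
             − 0.11·z(GWG) − 0.16·z(EBF months) + e
BMI        = 0.32·z(birth weight) + 0.14·z(ln Ins/Glu) − 0.40·z(age) + e
```

Coefficients are the trial's published standardized path estimates; paths
the published diagrams leave unlabeled (sex and age terms on the mediators,
the remaining covariates on the outcomes, IGF-1→growth) default to 0 and
are ordinary preset entries, so sensitivity analyses can turn them on. The
two mediator equations are shared by both growth models; where the two
published fits give slightly different mediator estimates, the weight-model
values are used as the single generating truth.

Residual variances are fixed so every endogenous variable has unit marginal
variance. Two routes exist:

* `solve_error_variances` — analytic path tracing over the declared graph
  with exogenous correlations derived in closed form from the dietary
  trajectory parameters (`trajectory_moments`). This validates preset
  feasibility (`InfeasiblePreset` if any explained variance ≥ 1).
* The generator itself uses the *realized in-sample* variance of each
  linear predictor, which makes the marginal variance exactly 1 in-sample
  and the standardized coefficients the exact generating truth for any
  regression-consistent estimator. The two routes agree to O(n^-1/2)
  (tested).

Natural units are obtained by affine maps (weight 10.6 ± 1.15 kg,
BMI 16.8 ± 1.35 kg/m², ln IGF-1 with median 50 ng/mL, σ_log 0.35, …).
Affine rescaling leaves standardized coefficients untouched, which is the
whole point of the construction. Length is derived as
`100·sqrt(weight/BMI)` so the BMI identity holds row by row.

### Dietary layer

Per-visit protein (and carbohydrate, fat, fruit/vegetable) intakes follow
group-specific mean trajectories with a per-infant tracking factor
(`visit_tracking = 0.55` of within-cell variance) plus visit noise. The
Nordic arm's protein reduction is largest at 12 mo (19 vs 29 g/d) and
smallest at 18 mo (34 vs 38 g/d), emulating waning adherence; energy is
computed as 4(P+C)+9F kcal plus noise so arms stay near-isocaloric.
Cumulative protein exposure is the trapezoid AUC of these records over the
nominal visit ages, exactly as the analysis side computes it, so generator
and analysis share one exposure definition.

Breastfeeding is a single per-infant latent threshold against a declining
probability curve (76.5% at enrollment, 71/39/20% at 6/9/12 mo, 8% vs 2%
by arm at 18 mo), which makes cessation monotone. Feed counts (meals,
snacks) are Poisson given continued breastfeeding.

### Metabolite layer

The panel has 52 named analytes with lognormal concentrations around
typical infant plasma medians. Leucine, isoleucine and valine load 0.95 of
their log-scale variance on a shared factor tied to recent protein, giving
pairwise correlations > 0.93 and a protein–total-BCAA correlation ≈ 0.45
before attenuation. Group shifts for the differential analytes are
parameterized as Wilcoxon effect-size classes and converted to normal
location shifts by `delta = sqrt(2)·Phi^-1(1/2 + r/sqrt(3))` (the
large-sample relation between the rank-biserial AUC and r for balanced
groups). Class targets are r = 0.28 (small), 0.40 (moderate), 0.60
(large) — the upper halves of the conventional bands, chosen once so that
analytes reported as trial discoveries at ~100/group remain reproducible
discoveries after FDR control. Shifts are applied at 12 mo only; the
18-mo panel differs between arms only through the (smaller) protein gap,
reproducing the observed attenuation.

Because the diet-mediated BCAA shift alone (0.45 × protein gap) falls
short of a "moderate" class, the preset tops the Nordic 12-mo BCAA latent
down directly — interpretable as a protein-*quality* channel the
intake-quantity path does not carry. All downstream equations consume the
realized BCAA values, so the fitted SEM remains correctly specified.

### Dropout

Loss to follow-up is logistic on standardized maternal prepregnancy BMI
(+0.35), maternal age (−0.35), breastfeeding at enrollment (−0.5) and arm.
The intercept and arm coefficient are solved by Gauss–Hermite quadrature
at preset build time so the expected attrition is 24% (Nordic) and 12%
(conventional). Dropouts keep rows up to their last attended visit; since
the SEM sample requires complete four-visit diet records, dropout removes
infants from the analysis frame rather than being imputed.

## 2. Estimators

### Cumulative intake

Trapezoid rule on (month, g/d) pairs at the nominal schedule 6-9-12-18,
intervals 6→12 and 6→18; only infants with all four records enter (no
imputation). Protein E% uses 4 kcal/g (config constant); the g/kg flag is
`protein/weight ≥ 1.05`, the energy flag strictly `> 15 E%`.

### Metabolome testing

* glog: `ln(y + sqrt(y² + λ))`, λ = 1 (concentration² units).
* PCA: SVD of the centered, unit-variance glog panel pooled over both
  timepoints. Contribution of variable j to component k is `100·v²_jk`
  (orthonormal loadings), summing to 100 per component; the reference line
  is 100/52. Score ellipses use the Hotelling form
  `2(n−1)/(n−2)·F_{2,n−2}(0.95)` on the 2-D score covariance.
* PERMANOVA: `SS_total = Σ_{i<j} d²_ij / n`, within-group analogue with
  1/n_g weights, pseudo-F on (g−1, n−g) df, p-value
  `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)` under unrestricted relabeling
  (999 permutations by default; matches the vegan-style partition, and is
  cross-checked against scikit-bio in the tests). Dispersion homogeneity:
  principal-coordinate embedding with signed negative-eigenvalue handling,
  distance to group centroid, one-way ANOVA F on those distances.
* Volcano: two-sided Mann-Whitney U per analyte — tie-corrected,
  continuity-corrected normal approximation by default, exact enumeration
  available (and used for n ≤ 8 oracles) — then Benjamini-Hochberg within
  the 52-analyte family of one timepoint. Effect size r = |Z|/√n with the
  tie-corrected Z. Rank tests are invariant to glog, so concentrations are
  reported untransformed.

### The SEM engine

All-observed RAM form: Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ, free cells listed
explicitly; exogenous variances/covariances live in Ψ (saturated among
exogenous by default). Discrepancy
`F(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p` with the (n−1)-divisor S;
`T = (n−1)·F` on `df = p(p+1)/2 − q`.

Numerics: estimation runs in a unit-variance internal metric (each
variable divided by its sample SD). Because every variable's variance is
free, the model family is closed under diagonal rescaling, so the optimum
maps back to raw units exactly (`b → b·sd_child/sd_parent`,
`ψ → ψ·sd_i·sd_j`) while the information matrix stays well-conditioned
when grams and log-ratios share a model. Starting values are per-equation
least squares computed from S — exact for just-identified recursive
models, so the optimizer only polishes; otherwise L-BFGS with the analytic
gradient (`dF = tr[W(Σ−S)W dΣ]`) followed by Fisher-scoring Newton steps
to a gradient ∞-norm below 1e-6 (`NonConvergence` otherwise).

Robust layer (complete data): casewise scores
`s_ik = ½(z_i'WΔ_kWz_i − tr(WΔ_k))`, sandwich covariance
`A⁻¹(Σs_is_i')A⁻¹` with A the expected information. The scaled statistic
divides T by `c = tr(UΓ)/df`, where Γ is the empirical covariance of
vech(z_iz_i') and `U = V − VΔ(Δ'VΔ)⁻¹Δ'V` with `V = ½D'(Σ̂⁻¹⊗Σ̂⁻¹)D`
(the Satorra-Bentler construction). A singular score second-moment matrix
is tolerated — balanced binary covariates make z² constant, a degenerate
fourth-moment direction — since the sandwich never inverts the meat;
`RankDeficientScores` is raised only when cases cannot span the parameter
space (n ≤ q).

Fit indices: the standard closed forms (CFI, TLI, NFI, IFI from the
closed-form independence baseline; RMSEA with a noncentral-χ² 90% CI;
SRMR over correlation-standardized residuals; GFI/AGFI from the
W-weighted residual quadratic form). "Robust" variants substitute the
scaled statistics T/c and T₀/c₀ into the same formulas — the convention
implemented here, stated to avoid ambiguity with shifted variants in other
software. Modification indices are univariate score tests,
`MI = (n−1)g²/(4·schur)` with the expected-information Schur complement,
plus the expected parameter change `−g/(2·schur)` (rescaled to raw units).

Standardized coefficients use model-implied SDs; their CIs come from the
delta method on the robust parameter covariance.

### The growth models

Both models share the mediator equations
`ln IGF-1 ~ z(protAUC) + ln BCAA + sex + age` and
`ln Ins/Glu ~ ln BCAA + sex + age`; the growth equation regresses the
outcome (weight in kg, or BMI in kg/m²) on z(protAUC), ln Ins/Glu,
ln IGF-1, birth weight, GWG, prepregnancy BMI, EBF duration, formula use,
sex, and age, with free covariances among all exogenous variables. That is
p = 12 observed variables, 65 free parameters, df = 13. The direct
IGF-1→outcome path is included by default (the hormone sits adjacent to
the outcome in the hypothesized diagram) with a switch to drop it; the
sensitivity of the protein path to this choice is itself tested. The 12-
and 18-mo rows of one infant enter as independent observations with age as
a two-level covariate — the same simplification as the analysis being
emulated; cluster-robust alternatives are out of scope and the limitation
stands (§4).

Assumption checks follow the simulated-quantile-residual idea: refit each
structural equation by Gaussian OLS, simulate n_sim response vectors,
place each observation by randomized rank among its simulations (uniform
under a correct model), then test uniformity (KS), dispersion (observed
residual variance against the simulated distribution, two-sided
permutation-style p), and boundary outliers (binomial).

### Descriptive comparisons

2×2 tables use Yates-corrected χ² (the printed attrition table reproduces
p = 0.013); continuous variables Welch's t; small binary outcomes the
conditional exact (hypergeometric) test by default with a literal
one-sample binomial alternative behind a flag, because "exact binomial
test" is ambiguous for a two-group comparison.

## 3. Calibration choices (made once, at design time)

* Recent-protein→BCAA link r = 0.45, inside the published "> 0.32" bound.
* Wilcoxon class targets at the upper halves of the bands (§1), so the
  trial's reported discovery set is reproducible at its sample size.
* Protein trajectories sized to Scandinavian complementary-feeding intakes
  with the adherence peak at 12 mo; within-cell SDs of 4–7.5 g/d.
* Gestational weight gain 14 ± 5 kg (standard obstetric range; the
  baseline table prints only maternal BMI measures).
* Problem sizes: acceptance-grade parameter recovery uses one cohort of
  5000/group (standardized-coefficient MC SE ≈ 0.01); calibration tests
  use 100–500 replicates at 40–400 infants, sized to keep the whole suite
  under a minute of simulation per test while leaving binomial CIs tight
  enough to be informative.

## 4. What the synthetic cohort does *not* emulate

* **No age gradient in weight.** The published diagram prints no age→weight
  path, and an age-dependent affine rescale would inflate Var(weight) and
  shrink every standardized coefficient below its printed value; synthetic
  12- and 18-mo weights therefore share one scale. BMI does carry its
  printed age effect (−0.40), so derived length grows with age.
* **Within-infant correlation** across the two pooled rows arises only
  through shared covariates, not through persistent unmeasured infant
  effects; SEs at trial scale are therefore mildly optimistic, exactly as
  in the emulated analysis.
* Metabolite-metabolite correlation structure beyond the BCAA block is
  absent; real panels have rich covariance families.
* Diet records are noiseless summaries — no reporting error, no
  food-composition-database error, no visit-age jitter.
* Passing recovery tests shows the *pipeline* is correct under its own
  generating assumptions; it cannot validate the causal claims on real
  data, where the published caveat stands: path arrows are hypothesized,
  not demonstrated, causal relationships.

## 5. Degenerate inputs and tie-breaks

* All-tied metabolite: U test returns p = 1, r = 0.
* Constant panel variable: dropped from PCA with a warning (scale
  undefined).
* 0/0 Canberra terms are skipped (scipy convention).
* Saturated SEM (df = 0): T = 0, incremental indices 1, RMSEA/SRMR 0,
  flagged `saturated`.
* PERMANOVA needs ≥ 2 groups with ≥ 2 members; the permutation p is
  floored at 1/(n_perm+1).
* Infants missing any of the four diet records are excluded from every
  AUC-dependent analysis — never imputed.
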