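# Methods

`twinlca` implements an analysis chain that links patterns of adolescent
lifestyle behaviour to biological aging in young-adult twins:

1. a **latent class analysis** (LCA) over mixed ordinal + continuous
   lifestyle indicators identifies behaviour patterns;
2. the **BCH three-step procedure** compares epigenetic aging measures
   across the latent classes without letting the outcome distort the class
   solution;
3. **twin biometric models** (ACE/ADE/AE/CE/E) decompose the variance of
   each aging measure into genetic and environmental parts;
4. a **shared-variance decomposition** combines 2 and 3 to quantify how
   much aging variance is carried by genetic and environmental factors
   *common* to the lifestyle patterns.

Because suitable individual-level twin data are access-restricted in
practice, the package ships a synthetic-cohort generator that reproduces the
statistical structure this chain assumes, together with a simulation oracle
that supplies ground truth for every estimator.

## Latent class model

The measurement model is a finite mixture with local independence.  With
mixing proportions `pi_k`, ordinal indicator `j` follows a class-specific
multinomial over its `C_j` categories and each continuous indicator (BMI at
three ages) a class-specific normal `N(mu_jk, sigma2_jk)`.  The observed-data
log-likelihood

    sum_i log sum_k pi_k prod_{j in obs(i)} f_jk(y_ij)

drops missing items from the product, which is full-information maximum
likelihood (FIML) and unbiased under missing-at-random (MAR).  Individuals
with no observed indicator are excluded (`n_effective`).

*Estimation.* EM with a two-stage multistart: every start initialises from
a random Dirichlet posterior, runs a short burn-in (default 30 iterations),
and the best few (default 5) continue to convergence.  Defaults: 50 starts,
relative log-likelihood tolerance 1e-6, at most 1000 iterations.  The
log-likelihood is non-decreasing across iterations (asserted in tests).
Class-specific BMI variances get a floor of 1e-4 times the marginal
variance; floor hits are flagged.  Ordinal parameters are unconstrained
category probabilities — the exact-likelihood equivalent of free
cumulative-link thresholds, without committing to a link function.

*Label switching.* Classes are reported in a canonical order: descending
mixing proportion, ties broken by ascending mean of the last continuous
indicator (BMI at 17).

*Selection statistics.* AIC = −2L + 2p, BIC = −2L + p·ln n, and the
sample-size-adjusted BIC with `ln((n+2)/24)`; `n` is the number of
contributing individuals (twins enter as individuals; the clustering only
affects standard errors, for which a family-clustered linearisation SE of
the class proportions is provided).  Class-enumeration tests compare K
against K−1 classes via `T = 2(L_K − L_{K−1})`: the unadjusted p-value
refers T to a chi-square with the parameter-count difference as df, and the
adjusted variant scales T by `1 + 1/(dp·ln n)` (a parameter-difference and
sample-size based correction in the spirit of the Lo–Mendell–Rubin
approximation).  The chi-square reference is *conservative* under the
mixture null — simulated type-I error at the 5% level is at or below
nominal — and p-values for strongly separated alternatives are effectively
zero, so the enumeration decision pattern is preserved even though the
exact reference distribution of commercial implementations is unpublished.
Classification quality is summarised by AvePP: the mean posterior
probability of a class among the individuals modally assigned to it.  With
tied posteriors the modal assignment takes the first index; a class with no
modal members has undefined AvePP (NaN).

## BCH distal outcomes

From the posterior matrix the classification-error matrix
`D[k,s] = sum_i p_ik 1[w_i=s] / sum_i p_ik` (modal assignment `w`;
a proportional variant is available) is inverted to `H = D^-1`.  Individual
`i` enters the secondary model with weight row `H[w_i,:]`; rows sum to 1
but can be negative, which is what undoes the attenuation of naive modal
assignment.  A near-singular `D` (entropy too low) is refused with a
remedy message.

The secondary model is weighted least squares of the outcome on K
class-indicator columns (no global intercept) plus covariates — sex coded
female = 1, age standardized within sample, pubertal development score on
its raw 1–3 scale; an adult-BMI adjustment is just one more covariate
column.  Standard errors come from a family-clustered sandwich with a
G/(G−1) small-sample factor; the overall test of equal class means is a
Wald chi-square with K−1 df (large-sample reference), and all pairwise
contrasts are reported with 95% and 99% CIs.  Standardized mean differences
divide each contrast by the *whole-sample* SD of the outcome — the
convention verified to reproduce published contrast tables from their
printed differences and marginal SDs (e.g. 2.70/3.24 = 0.83).

## Twin biometric models

Two-group (MZ/DZ) univariate models with a common grand mean and expected
covariance structure: `A` loads 1.0 in MZ and 0.5 in DZ pairs, `D` 1.0 and
0.25, `C` 1.0 and 1.0; total variance is the component sum.  Variance
components are parameterized directly and left unconstrained (negative
estimates allowed); standardized shares are computed from the unconstrained
solution with delta-method CIs from a numerical Hessian.  Pairs with one
missing member contribute their univariate marginal (FIML).  Opposite-sex
DZ pairs are pooled with same-sex DZ pairs; no sex-limitation models.  The
DE model is excluded (dominance without additive variance is biologically
implausible).  Optimization is Nelder–Mead on sufficient statistics from 5
jittered moment-based starts.

Fit indices are normal-theory (no scaled chi-square; scaling affects
p-values, not point estimates): the model chi-square compares against a
saturated model with a common mean, free per-member and per-group variances
and per-group covariances (7 parameters), giving df 3/3/4/4/5 for
ACE/ADE/AE/CE/E; CFI/TLI use the independence baseline (zero within-pair
covariance, common mean and variance — the E model), clamped to [0,1];
multigroup RMSEA is `sqrt(2)·sqrt(max(chi2−df,0)/(df·N))` with N the number
of individuals; SRMR is the RMS of standardized residuals between
complete-pair moments and model-implied moments; BIC = −2L + p·ln N.  The
model-comparison report flags the most parsimonious model whose chi-square
p exceeds 0.05 and whose CFI ≥ 0.95, RMSEA ≤ 0.06 and SRMR ≤ 0.08 pass
(ties by lower BIC; if nothing passes, lowest BIC).

## Shared-variance decomposition

For one outcome (pre-adjusted for sex, age and PDS): a no-covariate BCH
distal fit gives class means `mu_k`; the residual score is
`y_i − sum_k w_ik mu_k` with BCH weight rows by default (posterior rows by
configuration — which rows a black-box implementation uses for factor
scores is not observable, so both are offered).  The AE model is fitted to
the outcome ("total") and to the residual, and the decomposition reports

    shared genetic        (aTot2 − aRes2) / VarTot
    shared environmental  (eTot2 − eRes2) / VarTot
    unique genetic         aRes2 / VarTot
    unique environmental   eRes2 / VarTot

with `VarTot` taken from the total-fit model so the four shares sum to 1
exactly and the two shared parts sum to `Var(Model)/VarTot`.  Sampling can
make a shared estimate negative (`aRes2 > aTot2`); it is reported as-is
with a warning to keep the estimator unbiased across replicates, and a
clamp-to-zero option exists for presentation-style stacked figures.

An important subtlety: the class-conditional means absorb `E[A | class]`
whenever the outcome's genetic part overlaps the class liability, so the
residual genetic variance is below the generator's `a2` even when the
structural class means are equal.  The decomposition therefore measures
genetic *correlation* (confounding included), not a causal class effect —
this is exactly what makes it informative about pleiotropy.

## Synthetic cohort generator

One latent *class liability* per twin, `L = sqrt(h2)·g + sqrt(1−h2)·e`,
with `g` standard normal and correlated 1.0 within MZ and 0.5 within DZ
pairs; classes are the threshold discretisation of `L` at the quantiles of
the target proportions, so `class_liability_h2` is directly the liability
heritability and twin class concordance is analytic.  Given class, the
indicators are drawn independently.  Outcomes are
`class mean + covariate effects + A + E` with `Var(A)+Var(E)=1` (class
contrasts are in residual-SD units); a fraction `shared_a_frac` of the
genetic variance loads on the standardized class-liability genetic score,
the rest on an independent pair-structured genetic score.  Item
non-response is MAR: per-indicator Bernoulli with a logit shifted by sex
and age only.  Hidden truth (class labels, genetic scores) is emitted in a
separate sidecar, never in the cohort file.

*Default five-class configuration.*  Class proportions
(0.320, 0.199, 0.228, 0.095, 0.159) — renormalized, as the printed vector
sums to 100.1% — with class-conditional profiles of a healthy/active class,
a low-normal-BMI class, a high-normal-BMI class, a high-BMI class and an
unhealthiest-lifestyle class (printed probability rows renormalized
likewise).  Class-conditional BMI SDs are not published; the generator uses
a common within-class SD per timepoint derived from the marginal SDs
(2.6, 2.7, 3.0 kg/m²) minus the between-class variance implied by the class
means and proportions — the maximal within-class spread consistent with the
printed margins.  Item-missingness rates (1.5–19%) reproduce the published
per-indicator observation counts; liability heritability defaults to 0.5
(moderate, as typical for behavioural phenotypes); the default outcome is a
GrimAge-style age acceleration with AE structure a² = 0.73 and class
contrasts from the published between-class differences rescaled to
residual-SD units.  A compact two-class configuration (four 3-category
indicators, separation set so classification entropy is near 0.8 at 365
pairs) supports fast replicate experiments; its `shared_a_frac` can be
solved by bracketed root-finding against the oracle to hit a target
shared-genetic proportion.

*Oracle.*  `true_shared_proportions` simulates ≥10⁶ MZ and DZ latent pairs,
computes population pair moments of the outcome and of the residual against
the population class-conditional means, and fits the AE moment structure to
each (Falconer's `2(c_MZ − c_DZ)` is the optimizer start).  This is the
population value of the pipeline's own estimand, which is what recovery
tests should target.

*What the generator does not emulate.*  Local independence is exact in the
generator but only approximate in real questionnaire data: real BMI tracks
strongly within person across waves, and substance-use items correlate
beyond class.  Model-based posteriors computed under (wrongly) assumed
independence are overconfident on such data, which inflates AvePP.  On
faithful locally-independent data the Bayes-optimal minimum class AvePP of
the default configuration is ≈ 0.71 with missingness (≈ 0.75 without), so
published real-data AvePP floors near 0.78 are not reachable by any
estimator here — fitted solutions sit at 0.69–0.75.  Passing recovery
tests therefore validate the estimators under the stated generating model,
not the exact classification-quality diagnostics of any particular real
data set.  The generator also omits longitudinal within-person
autocorrelation beyond class, CpG-level methylation data, and
clock-specific measurement error.

## Preprocessing measures

Beta values `M/(M+U+100)`; age acceleration as the OLS residual of
epigenetic age on chronological age; outlier screening recodes values more
than 5 SD from the mean as missing in a single pass (mean and SD computed
once on the input); PDS is the mean of five 1–3 items; covariate
adjustment is OLS residualisation with listwise handling of missing
covariates.  Twin ICCs use the double-entry Pearson correlation on complete
pairs (one-way random-effects ANOVA estimator available) with a Fisher-z CI
using the number of complete pairs; no cross-measure nesting correction is
applied to these CIs.

## Problem sizes and numerical choices

The replicate experiments run at the sizes the estimators are designed for:
5-class LCA recovery on cohorts of 5114 individuals (20 replicates),
AE recovery at 154 MZ + 211 DZ pairs (500 replicates), end-to-end
shared-variance recovery on 365-pair cohorts (200 replicates per generating
truth, with the compact two-class configuration standing in for the full
battery), and null calibrations at 200–500 replicates.  EM multistart
settings for replicate work (30 starts, burn-in 50, top 6 polished,
tolerance 1e-7) were chosen so that independent reruns land on the same
solution; single showcase fits use 50 starts.  Degenerate inputs are
rejected with messages naming the offending row/column (IO), class
(empty-class BCH), or remedy (near-singular D, inadequate starts in the
enumeration tests).

## Known limitations

* The enumeration-test reference distribution is an approximation; only its
  conservatism and decision pattern are guaranteed by tests.
* Normal-theory chi-square throughout; no Satorra–Bentler scaling.
* The biometric saturated model constrains the mean structure (common grand
  mean), so its chi-square tests the covariance structure given that mean
  model.
* Delta-method CIs for standardized shares can be poor near boundary
  estimates; a profile-likelihood option is not implemented.
* The ICC CI ignores the nesting of the two twins across multiple measures.
* Classification noise inflates the residual scores' variance, and that
  inflation lands almost entirely in the residual's non-shared
  environmental component (the noise is uncorrelated within pairs given the
  true classes).  The *environmental*-shared proportion is therefore biased
  toward zero (and can go clearly negative) at imperfect entropy, and
  `Var(Model)/VarTot` is correspondingly understated, while the
  *genetic*-shared proportion — driven by pair covariances — is close to
  unbiased, as the end-to-end recovery tests verify.
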