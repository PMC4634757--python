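# Methods

`follisig` models a transcriptomic signature of early ovarian
folliculogenesis: gene expression measured in laser-capture-microdissected
oocytes (O) and granulosa cells (GC) across the four earliest follicular
stages — primordial (PD), primary (PM), secondary (SC) and small antral
(SA) — plus multi-tissue RNA pools (MT) used as a somatic-specificity
background. This note describes the models, their assumptions, the
synthetic-data generator, and the numerical choices.

## Negative-binomial differential expression

Counts for gene *g* in sample *j* are modelled as NB with mean `s_j q_gj`
and variance `mu + alpha mu^2` (size factors `s_j`, dispersion `alpha`).

**Size factors** are median-of-ratios: `s_j = median_g k_gj / geomean_g`,
over genes with nonzero counts everywhere (an explicit fallback to a
pseudo-reference over half-nonzero genes exists but is opt-in). The
estimator is equivariant on factor ratios: doubling one sample's counts
doubles its factor relative to every other sample.

**Dispersion** is method-of-moments per group: within each stage x
compartment group with >= 2 replicates, `alpha_g = (v - m c) / m^2` where
`v`, `m` are the group variance/mean of normalized counts and `c` the
group mean of `1/s_j`; per-gene values pool the groups by residual df.
Scaling group-by-group keeps regulated genes from inflating their own
dispersion. Because 26 residual df make gene-wise estimates noisy — and
underestimates make every test anti-conservative — the default
(`share="maximum"`) takes, per gene, the maximum of the gene-wise value
and a mean-dispersion trend `alpha(mu) = a0 + a1/mu` fitted across genes;
`share="none"` gives the raw gene-wise values. The floor is 1e-8.

**Pairwise exact test.** Group sums `K_A`, `K_B` are moment-matched NB
under the pooled null mean; conditioning on `K = K_A + K_B`, the two-sided
p-value is the total probability of all partitions `(k, K - k)` no more
likely than the observed one (summed, not tail-doubled), divided by the
mass of all partitions. The partition sum is computed in log space over
the full range `0..K` (ties counted with relative tolerance 1e-8), so it
is exact rather than truncated; `K = 0` returns p = 1. Against an
independent plain-Python enumeration oracle it agrees to < 1e-13.

**Stage LRT.** Per compartment, `count ~ stage` vs `count ~ 1` are NB
log-link GLMs with fixed dispersion and log size-factor offsets, fitted by
IRLS (statsmodels); twice the log-likelihood difference is referred to
chi-square with (stages - 1) df. The test is run per compartment because
the design's stage contrasts are intra-compartment. On 2,000 simulated
null genes the p-values are uniform to KS < 0.02.

**Selection rules.** Stage-regulated genes: GLM BH-FDR < 5% AND some
pairwise p < 1% AND fold change > 2 (ratio > 2 or < 0.5). Biomarkers of a
stage x compartment group: one exact test of the group against all other
samples pooled (MT included), BH over genes, FDR < 5% and fold change > 10
(oocyte targets) or > 3 (granulosa targets). `x/0` is reported as +inf and
passes any threshold; `0/0` never selects. Transition summaries count
up/down genes (p < 1%, FC > 2) at PD→PM, PM→SC, SC→SA per compartment.

## qPCR quantification

Amplification efficiency comes from a serial-dilution standard curve:
least-squares slope of Ct on log10 input, `E = 10^(-1/slope)`; a
non-negative slope raises a quality failure. Relative quantities are
Pfaffl ratios `E^(Ct_cal - Ct)`; the default calibrator is the per-gene
mean Ct over detected samples (configurable to a named sample).
Normalization divides each sample by the geometric mean of its reference
genes; a sample with an undetected reference is excluded with a warning.
Reference stability is geNorm's M (mean SD of pairwise log2 ratios on
complete cases), with the exclusion ranking produced by iteratively
dropping the largest-M candidate. Detection calls: Ct numeric, below the
cycle cutoff (default 40), and at least 3 cycles below a matched negative
control when one exists — the calling rule is a package convention, kept
configurable. Technical replicates can be averaged before or after
normalization via `average_technical_replicates`; the orders differ only
when replicates disagree and neither is asserted as canonical.

## The hurdle mixed model

Presence and level are modelled separately, sharing an architecture but no
parameters. For gene g, stage s, compartment c, replicate k:

* presence: `z ~ Bernoulli(logit^-1(beta[s,c] + b[g,s] + u[g,c]))`
* level (where detected): `y^(1/4) = mu[s,c] + b'[g,s] + u'[g,c] + eps`,
  `eps ~ N(0, sigma^2)`

with `b_g ~ MVN(0, Sigma_stage)` (4x4 unstructured — the object of
interest, carrying across-stage correlations of the gene effects) and
`u_g ~ MVN(0, diag(tau_O^2, tau_GC^2))`. The fourth root is a variance
stabilizer for strictly positive relative quantities spanning orders of
magnitude. Cells in which no replicate is detected contribute one
augmented zero-expression record to the level data, encoding "absence
means null expression". Replicates are exchangeable residuals, not their
own random effect.

**Identifiability.** If both covariance blocks were unstructured the
decomposition would be aliased: `(Sigma_s + aJ, Sigma_c - aJ)` yields the
same marginal likelihood for any feasible `a`. A diagonal compartment
block removes the aliasing (cross-compartment covariances identify
`Sigma_stage` alone); the full 2x2 block and a fully unstructured 8x8
cell covariance are available behind `FitConfig(full_cell_cov=True)` /
`structure="unstructured"` for users who accept the caveat.

**Estimation.** The Gaussian part is fitted by exact maximum likelihood
via EM: the per-gene random-effect posterior is Gaussian in closed form;
M-steps update the cell means, the structured covariance (block/diagonal
projection of the posterior second moment) and `sigma^2`. The marginal
log-likelihood is monotone and convergence is declared at a relative
change below 1e-7 (max 500 iterations). The logistic part uses
Laplace-approximated ML: for fixed covariance, fixed effects and all
conditional modes are maximized jointly by blocked Newton with
step-halving (solved through the Schur complement on the 8 fixed effects;
the fixed effects are profiled inside the penalized problem, as in the
standard GLMM Laplace implementations); the covariance is then updated by
EM on the modes plus their Laplace curvatures, accepting a step only if
the Laplace objective does not decrease, with over-relaxation along
accepted EM directions to escape the terminal crawl near correlation
boundaries. Covariance inverses/log-determinants use eigenvalue flooring
so boundary estimates (correlation ~1) stay usable. On a 2-gene, 2-stage,
2-replicate instance with small fixed covariance the Laplace marginal
log-likelihood matches adaptive 2-D quadrature to < 1e-6.

Complete separation (an all-detected or all-undetected cell) engages a
ridge of 1e-4 on the fixed effects and is flagged; fixed-effect standard
errors come from the Schur complement of the joint penalized Hessian
(level part: GLS information), ignoring covariance-estimation uncertainty,
as is standard for GLMMs. Variance-component diagnostics refit with the
stage or compartment block removed and refer twice the log-likelihood drop
to chi-square with the freed parameter count — conservative at the
boundary, which only understates significance.

## Stage prediction

With empirical-Bayes plug-ins `p[g,s,c]` and `mu[g,s,c]` (fixed effects +
conditional modes), the posterior over stages for a new vector in
compartment c is

    P(s | obs) ∝ prior(s) · Π_g p^z (1-p)^(1-z) · Π_{z=1} N(y^(1/4); mu, sigma)

computed in log space and normalized over {PD, PM, SC, SA}; the
binary-only variant drops the Normal term. The prior defaults to uniform.
Hard calls are posterior argmax with ties broken toward the earlier stage
and flagged. Predictive ability is assessed in-sample, as in the original
study: for each (stage, compartment) cell, 100 new vectors are assembled
by drawing, per gene, one observed replicate's (z, y) pair uniformly at
random (z and y always jointly), then scored through the equations.
Plug-in prediction deliberately ignores random-effect uncertainty; the
posterior-equation tests compare against a brute-force product-form Bayes
enumeration to 1e-10.

## Synthetic data

The generator reproduces the study design: 8 stage x compartment groups
with 4 replicates (3 for primordial oocytes) and 3 MT pools — 31 LCM
samples plus 3 pools.

*Counts* are NB (`Var = mu + alpha mu^2`) with baseline mean 100 and
dispersion 0.2 — typical of moderately expressed genes in small LCM
designs. A chosen fraction of genes carries a signed log2 effect from a
random onset stage onward, in both compartments; MT pools stay at
baseline. A companion generator plants group-exclusive markers (default
50-fold) for the biomarker filter.

*Biomarker panels* follow the hurdle model exactly: per-gene stage vectors
drawn from the requested 4x4 covariance and diagonal compartment shifts,
detection logits in [-1.5, 1.5] and fourth-root means in [1.6, 2.5] across
the cell grid (relative quantities of roughly 6-40 after normalization),
residual sd 0.5. Binary stage variance defaults to 4 (markers switch
between near-certain detection and near-certain dropout across stages)
and level stage variance to 1. The binary and level gene effects share a
latent factor with coupling 0.95: qPCR dropout is, physically, censoring
of low abundance, so a gene undetectable at a stage is also lowly
expressed there. This coupling is what makes the null-expression
augmentation of the level model coherent with the generator — with
independent parts a silent cell could carry a high latent level and the
augmented zeros would bias the level fixed effects. Fourth-root draws
below zero (rare under the defaults, and concentrated in cells that drop
out anyway) are clipped at zero.

Panel archetypes used by the validation studies: `correlated_stages`
(single-factor stage correlations, e.g. corr(PD,PM)=0.95,
corr(PD,SA)=-0.9, anchored at PD), `separated_panel` (independent large
stage effects, tight residual — a strongly discriminating signature) and
`pd_pm_binary_confounded` (PD and PM share detection parameters *and* the
dropout realization per compartment/replicate, so presence/absence is
uninformative for that pair by construction while levels still separate
all stages).

What the generator does not emulate: sequencing depth variation beyond
size factors, mean-dispersion trends, gene-gene correlation in counts,
amplification bias, plate/batch effects, and real dropout mechanisms
beyond the logistic model. Passing tests therefore demonstrate that the
chain recovers what its own model classes generate at the study's scale —
not performance on tissue.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` run: posterior-equation
equivalence with brute-force Bayes (panels up to 3 genes); hurdle
parameter recovery on 24-gene panels over 20 seeds (mean stage
correlations within 0.15 of truth; ~90% of fixed effects within 2 SE);
the resampling studies at 100 vectors per cell (full-model mean true-stage
posterior ~1.0; binary-only PD mass split ~0.5/0.5 on the confounded
panel); NB calibration on 2,000 null genes (GLM KS ~0.02; exact-test
rejection at 1% within binomial noise of 1%) and exact-vs-enumeration
agreement over all totals <= 200; selection recall ~0.96 on 100 planted
4-fold effects among 2,000 genes with false positives inside the BH
budget; exact biomarker recovery (3 planted 50-fold genes among 500);
qPCR efficiency recovery to 1e-6 and geNorm noisy-reference exclusion in
>= 95/100 runs; and byte-identical pipeline reruns. These sizes were
chosen to make each Monte-Carlo check decisive at desk scale.

## Known limitations

- Laplace ML for the logistic part is biased for small panels near
  correlation boundaries; estimated correlations of 0.95 typically come
  back around 0.90-0.93 at 24 genes.
- The level model treats augmented zeros as ordinary Gaussian
  observations (the study's convention); they are formally a
  misspecification whenever a silent cell's latent level is far from zero.
- Plug-in posteriors understate uncertainty relative to full integration
  over random effects; in-sample resampling mildly favours the true cell.
- The exact test's NB convolution uses moment matching of group sums, the
  standard approximation for unequal size factors.
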