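# Methods

## The experimental design being modelled

A hemiclonal analysis expresses each of a panel of haploid genomes
("hemigenome lines", reference panel size 39) in many individuals of both
sexes, against random genetic backgrounds, and measures adult fitness under
three operational sex ratios (MB 24♂:8♀, EQ 16:16, FB 8:24). Because each
line's haplotype is identical across its carriers, the between-line variance
estimates (half) the additive genetic variance, and doubling the
between-hemiclone variance converts it to the additive scale — hence the
heritability h² = 2σ²_g/(σ²_r + σ²_g).

Each sex × sex-ratio cell is assayed on two replicate days; per line and day
there are 7 female adult-competition vials (fitness = eggs laid in 18 h by
the 2 focal females) and 5 male vials (fitness = proportion of red-eyed
progeny among all progeny of the vial's 7 dams, kept as integer counts
`red`/`total`).

## Line-average pathway

1. male vial proportions → arcsin√p (variance-stabilising for proportions);
   female egg counts enter untransformed;
2. divide every value by its assay-day mean (removes multiplicative day
   effects);
3. per line × cell: mean over vials within each day, then the mean of the
   two day means (equal day weights regardless of vial counts — an
   unbalanced design therefore does *not* tilt a line's mean toward its
   better-sampled day);
4. scale and centre each of the six cell columns (sample SD, n−1).

Pearson correlations between columns give r_w,g,mf (within a ratio, across
sexes) and the across-ratio genetic correlations (within a sex). The
sexually antagonistic decomposition rotates each (W_F, W_M) plane by 45°
anti-clockwise; on exactly standardised columns the antagonistic variance
proportion is (1 − r)/2, an identity the tests verify and exploit.

Missing line × cell entries propagate as NaN and every correlation is
pairwise-complete with its effective n reported.

## Stratified bootstrap

Confidence intervals resample vial records with replacement independently
within every sex × line × day stratum, preserving stratum sizes, and re-run
the entire pipeline (transform, day-mean division, two-step averaging,
re-standardisation) per replicate; 95% intervals are percentile (linear
interpolation), with BCa (jackknife-over-lines acceleration) behind a flag.
Differences between two sex ratios are computed per replicate on the same
resampled table.

**What these intervals are and are not.** Because resampling is within
line × day strata, the bootstrap conditions on the realised panel of lines
and on the realised day × line effects: its spread reflects vial-level
measurement noise only. It omits (i) line-sampling variance — at 39 lines
roughly (1 − r²)/√39 ≈ 0.13 for a correlation near 0.4 — and (ii) the
attenuation bias discussed below. A simulation study in the acceptance
suite measures the coverage of the 95% interval for the generating
r_w,g,mf at ≈ 0.48, far below nominal. This is a property of the method
(which follows the source analysis exactly), not of the implementation;
these intervals should be read as describing measurement repeatability of
the panel at hand, not uncertainty about the population parameter.

**Attenuation.** Line means carry vial-level noise, so line-average
correlations are biased toward zero by the factor √(rel_F · rel_M), where
rel = σ²_g/(σ²_g + σ²_meas/line). With the reference variance fractions and
vial counts this factor is ≈ 0.8 (females) × 0.7 (males under FB), which is
why the parameter-recovery acceptance test reports line-average estimates
~0.07–0.12 below the generating correlations — the same phenomenon visible
in the motivating study as the gap between its line-average and
animal-model estimates. The mixed models below model the vial noise
explicitly and do not share this bias.

## REML mixed model

Standardised fitness (per-day scale/centre; arcsin√ males first) is fitted
with fixed Sex + Sex.Ratio + Sex:Sex.Ratio (cell-means coding) and
independent random intercepts for line, line:sex, line:sex_ratio and
line:sex:sex_ratio. All random terms key on line, so the marginal
covariance is block diagonal by line; the REML criterion
log|V| + log|X'V⁻¹X| + y'Py is accumulated block-wise with its exact
gradient, and optimised over log-variances (L-BFGS-B, three fixed starts,
criterion tolerance 1e-8; boundary estimates snap to 0 and are reported as
singular fits, not errors). Balanced one-way layouts reproduce the
classical ANOVA estimators to ~1e-9, and the full model agrees with
statsmodels' MixedLM (an independent implementation) to < 0.01.

The ANOVA-like table refits the model without each random term:
LRT = 2(ℓ_full − ℓ_reduced), Df = 1, p from the χ²₁ upper tail. Testing a
variance on its boundary makes this p conservative; the 50:50
χ²₀:χ²₁ mixture (p halved) is available via `mixture=True`. The χ²₁ default
matches the source study's tooling.

## Bayesian multivariate animal model

One joint model over all six cells (a per-ratio model would leave the
across-ratio genetic covariances undefined):

    W = μ(cell) + L(line, ·) + D(day, line) + ε,
    L ~ MVN(0, G)  (unstructured 6×6),  D ~ N(0, σ²_dl),
    ε ~ N(0, σ²_r[cell]).

All conditionals are conjugate; the Gibbs sampler updates cell means, line
vectors (batched 6-d Gaussian solves), day × line scalars, G by
inverse-Wishart, and scalar variances by inverse-gamma. Lines missing a
cell are handled automatically: the cell component of L is then informed
only through G (conditioning, as in multivariate animal models).

Priors: G ~ IW(0.01·I, 7); scalar variances Inv-Gamma(10⁻³, 10⁻³). The IW
scale is deliberately far below the unit data variance — an identity-scale
prior adds a full unit of pseudo-sum-of-squares per cell, repelling genetic
variances from zero (null panels then show h² medians ≈ 0.15) and inflating
small variances by ~30%. The source study does not state its priors, so
posterior summaries of its data are reproducible only approximately by
construction.

Defaults are 3 chains × 60,000 iterations, 10,000 burn-in, thin 50;
effective sample sizes (arviz) below 200 trigger a warning. Posterior
means are insensitive to chain length well before the default (stable to
< 0.01 between 1,500 and 15,000 iterations on reference panels), though
small male variances and σ²_dl mix slowly and need the longer runs for
tight interval estimates. Derived draws — h² = 2σ²_g/(σ²_r + σ²_g) (the
day × line term is *excluded* from the denominator, following the printed
formula, so draws can exceed 1) and correlations from G — are computed per
draw, guaranteeing PSD-consistent correlations in [−1, 1].

## Synthetic panels

`simulate()` draws, per line, a 6-vector of cell effects from G; per
(cell, day) a day effect; per (cell, day, line) a day × line effect; and
per vial a cell-specific residual, all Gaussian on a latent scale. Female
vials realise eggs ~ NegBin(mean = 60·e^latent, size 50 — variance/mean
≈ 2, mild beyond the vial-level latent noise since most biological
overdispersion is already the vial effect); male vials realise total as
7 Poisson(30) broods and red ~ Binomial(total, logit⁻¹(latent)). RNG
streams are split hierarchically so changing vial counts does not perturb
line effects under the same seed; the realised line effects are attached to
the returned table for recovery studies.

The reference scenario takes its genetic correlations (intersexual
0.3805/0.4027/0.2515; across-ratio female 0.7493/0.7688/0.8421, male
0.6995/0.5567/0.5415) and its variance *fractions* (from the reference
heritabilities via h² = 2σ²_g/(σ²_g + σ²_r), day × line fraction 0.0353)
from the motivating study's estimates. Across-sex-across-ratio
correlations are not separately reported there and are set to
½(r_mf[a]·Rm[a,b] + r_mf[b]·Rf[a,b]) — the intersexual correlation
propagated through each sex's across-ratio structure, averaged — which is
positive definite (smallest eigenvalue 0.12 on the correlation scale).
Because per-day standardisation removes the absolute latent scale, that
scale is a free realism parameter: latent SD scale 0.45, giving a raw
female fecundity CV ≈ 0.5.

**What a green test does not establish.** The links distort variance
fractions between the latent and observed scales (convexity of exp;
flattening of logit→arcsin), and count noise adds residual variance the
latent parameters do not name. Recovery tests therefore see female
heritabilities ~0.2 below their latent generating values, and the
line-average correlations the attenuation above. The generator emulates
design structure and realistic noise, not every feature of real data: no
vial-loss mechanism beyond optional unbalanced designs, no viability
selection, no common-environment covariance beyond the day terms.

## Numerical conventions

Sample SDs use n−1 throughout (the standardisation constant scales all
downstream variances). Proportions outside [0, 1] by ≤ 1e-12 are clamped;
larger excursions are data errors. Quantiles are linear-interpolation
(numpy default) for bit-reproducibility given a seed. Male vials with zero
scored progeny have an undefined proportion and are dropped at ingest with
a warning; a positive red count with zero total is an error. Day labels
are validated as nested within one sex × sex-ratio cell, since each assay
was set up on its own day.
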