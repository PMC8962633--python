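# hemifit

Quantitative genetics of sex-specific fitness in hemiclonal *Drosophila*
panels. `hemifit` implements the analysis chain for experiments in which a
set of "hemigenome" lines — haploid genomes propagated intact and expressed
against random genetic backgrounds — is assayed for male and female adult
fitness under several operational sex ratios, and the question is how much
of the genetic variation in fitness is shared, sexually antagonistic, or
environment-specific.

## What it computes

For vial-level records (female fitness = 18-h egg count of the two focal
females of an adult-competition vial; male fitness = proportion of sired
red-eyed progeny pooled over the vial's seven dams) the package provides:

* **Line-average pathway.** Male proportions are arcsin-square-root
  transformed, values are divided by their assay-day mean, vials are
  averaged per line within each replicate day and the two day averages are
  averaged; per-cell standardised line means give the intersexual genetic
  correlation for fitness r<sub>w,g,mf</sub>, the across-sex-ratio genetic
  correlations, and the sexually antagonistic variance decomposition via the
  45° rotation

      W_C = ( W_F + W_M) / √2,   W_A = (−W_F + W_M) / √2,

  for which the antagonistic variance proportion equals (1 − r)/2 on
  standardised columns. Uncertainty comes from a stratified bootstrap that
  resamples vials within every sex × line × day stratum and re-runs the
  whole pipeline per replicate.
* **REML mixed model.** Standardised fitness ~ Sex + Sex.Ratio +
  Sex:Sex.Ratio with random intercepts for line, line:sex, line:sex_ratio
  and line:sex:sex_ratio, fitted by an in-repo block-wise REML with exact
  gradients, plus an ANOVA-like table of χ²₁ likelihood-ratio tests per
  random term.
* **Bayesian multivariate animal model.** A Gibbs sampler for
  W = μ(cell) + L(line, cell) + D(day, line) + ε with L ~ MVN(0, G) over the
  six sex × sex-ratio cells, a scalar day × line variance and cell-specific
  residuals; posterior summaries of G yield genetic correlations and the
  hemiclone heritabilities h² = 2σ²_g / (σ²_r + σ²_g).
* **Synthetic panels.** `simulate()` draws vial-level data from a known
  G-matrix with day, day × line and residual noise through count links, so
  every estimator has a parameter-recovery test surface.

## Worked example

```python
import hemifit as hf

params = hf.default_reference_params(seed=1)   # 39-line reference panel
table = hf.simulate(params, seed=1)
res = hf.LineAverageModel(table).fit(n_boot=2000, seed=1)
print(res.summary())
```

```
Line-average statistics (stratified bootstrap, n_boot=2000, seed=1)
===================================================================
    statistic  estimate   lower  upper  n_lines
   r_wgmf[MB]    0.2739  0.0606 0.3911       39
   r_wgmf[EQ]    0.4647  0.2683 0.5405       39
   r_wgmf[FB]    0.1645 -0.0578 0.3146       39
  sa_prop[MB]    0.3630  0.3045 0.4697       39
  ...
```

The positive r<sub>w,g,mf</sub> estimates say that hemigenomes good for one
sex tend to be good for the other in this panel; `sa_prop` is the fraction
of line-mean variance on the antagonistic axis (0.5 means no net
concordance; values above 0.5 indicate predominantly opposing effects).
With only 39 lines the estimates scatter visibly around the generating
values (0.3805 / 0.4027 / 0.2515 here) — see `docs/methods.md` on
measurement-error attenuation. The mixed models run the same way:

```python
lmm = hf.FitnessLMM.from_table(table).fit()
print(lmm.lrt_random_terms())        # ANOVA-like random-term LRT table
vc = hf.AnimalModelVC.from_table(table).fit(chains=2, iters=20_000,
                                            burn_in=5_000, thin=25, seed=1)
print(vc.summary())                  # posterior G, h2, correlations
```

A command line mirrors the library: `hemifit simulate | validate |
line-stats | bootstrap | lmm | vc | run`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
simulates the reference panel from the given seed and runs the complete
analysis — validation, line-average statistics with bootstrap intervals and
the MB−FB difference, the REML LRT table, and the Bayesian
variance-component posterior — printing each summary table as it goes.

## Data format

Long CSV, header `line,sex,sex_ratio,day,vial,eggs,red,total`; `sex` ∈
{F, M}, `sex_ratio` ∈ {MB, EQ, FB}; `eggs` only on female rows, `red`/`total`
only on male rows; day labels belong to exactly one sex × sex-ratio cell.
To convert a supplementary spreadsheet, map its columns onto this schema
(one row per adult-competition vial, male counts kept as integers rather
than proportions) and read it with `hemifit.read_fitness_table`.
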