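# Methods

This note documents the statistical model, the choices made where the design
was genuinely open, and what the synthetic-data generator does and does not
emulate.

## RTA dispersion estimation and divided counts

Estimated transcript counts are quasi-Poisson overdispersed under technical
resampling because reads are assigned probabilistically among overlapping
transcripts. For transcript *t* with per-sample resample matrices
(*B* columns each), the estimator pools a Pearson-type statistic over
samples *i* with positive resample mean `ybar_ti`:

```
D_t  = sum_i sum_b (y_tib - ybar_ti)^2 / ybar_ti
r_t  = sum_i (B - 1) * 1[ybar_ti > 0]
tau_t = max(floor, (D_t + prior_df) / (r_t + prior_df))
```

Defaults: `prior_df = 3`, `floor = 1`. The shrinkage target 1 encodes that
unambiguous transcripts carry no RTA overdispersion; the floor guarantees
division never inflates counts. Samples with zero resample mean contribute
no df (the Pearson term is 0/0). Both knobs are exposed on the CLI
(`--prior-df`, `--floor`, with `--floor 0` disabling flooring for
methodological experiments). With `B = 100` and six samples the estimator
recovers true `tau` in {1, 2, 5} with median relative error below 10% for
transcripts with mean count >= 10.

Divided counts `z = y / tau` are then treated as ordinary counts: library
sizes are the column sums of `z`, normalization factors start at 1.

## Filtering and normalization

Filtering operates on divided counts (division happens first). A transcript
is kept when its CPM — computed on effective library sizes — reaches
`min_count * 1e6 / median(effective lib)` in at least as many samples as the
smallest group, and its total count reaches `min_total_count`. Defaults
(10, 15); the lenient mode (1, 5) retains transcripts with one count in half
the samples of a balanced design. The rule is implemented directly as stated
rather than chasing any particular implementation's internal tolerance
constants; a relative tolerance of 1e-10 guards float round-off at the
cutoff boundary.

TMM normalization uses the published defaults: reference sample closest to
the mean upper-quartile CPM, 30% two-sided trim on M-values, 5% on
A-values, inverse delta-method variances as weights, factors rescaled to
geometric mean 1. Effective library size = library size x factor; it is the
CPM denominator and the GLM offset.

## The lm backend

`log2((z + 0.5) / (efflib + 1) * 1e6)` is modelled by transcript-wise
weighted least squares. Precision weights come from a mean-variance trend:
per-transcript OLS residual sd on the sqrt scale, lowess-smoothed (span
0.5) against average log-CPM, evaluated at each observation's fitted value
and raised to the power -4, clipped to [1e-6, 1e6]. One trend pass and one
refit; the trend is not recomputed after the residual-df adjustment, and
fewer than 10 transcripts (or a degenerate trend) falls back to unit
weights with a warning. Residual df are `(n - p) - sum_k (m_k - 1)` over
treatment groups of size `m_k` whose counts are all exactly zero — those
residuals are structurally zero and would otherwise overstate precision —
floored at 0.

## The nbglm backend

A single global NB dispersion `phi` is shared by all transcripts; gene-level
quasi-dispersions multiply the quadratic variance function. `phi` is
estimated by maximizing a pooled *adjusted* profile likelihood over
`phi` in [1e-6, 10] (golden-section on the log scale): the summed NB
log-likelihood at the fitted means minus half the log-determinant of each
transcript's expected information. The adjustment matters: the unadjusted
profile likelihood absorbs the df spent on estimating group means and
underestimates `phi` by roughly `(m-1)/m` per group at small group sizes,
which is material at n = 3-5 per group. Fitted means are taken from Poisson
fits; for group-factor designs they equal the NB fitted means at any `phi`.
Transcripts with mean count below 1 are excluded from the objective.

Per-transcript fits are log-link IRLS (max 50 iterations, relative deviance
change < 1e-8), coefficients stored on the natural log scale and reported as
log2, unscaled covariance from the inverse expected information at
convergence. All-zero transcripts get a linear predictor clamped at -745
(natural log), fitted means ~0 and deviance ~0. Residual df are adjusted
continuously: each observation contributes `1 - P(Y=0 | mu, phi)` effective
df, so very small positive fitted values also shed df; the bias-adjusted
mean deviance is `s^2 = deviance / adjusted df` with no further deviance
correction — the adequacy of this choice is verified by null-simulation
uniformity rather than bit-compatibility with any reference implementation.

Fitted TPMs are `(tau_t / L_t) exp(x_i' beta_t)` (library offsets excluded)
scaled by one global constant so the geometric mean of per-sample totals is
1e6, preserving all fold-changes; within-gene column shares give usage
proportions.

## Empirical Bayes and the DTU tests

Gene-pooled variances `s_g^2 = sum d_gt s_gt^2 / d_g` are shrunk by
moment matching on `e = log s^2 - psi(d/2) + log(d/2)`: the mean identifies
`s_0^2` given `d_0`, the excess of `var(e)` over `mean(psi'(d/2))` equals
`psi'(d_0/2)`, inverted by Newton on the trigamma (initialized at
`0.5 + 1/x`, converges in a handful of iterations). Non-positive excess
variance, or `d_0 > 1e7`, is treated as an infinite prior df. A `winsorize`
flag (90% winsorization of `e`) offers outlier-protected hyperparameter
estimation; default off. Genes with zero pooled df receive the prior
variance. Hyperparameters are estimated across the genes being tested
(those with at least two usable transcripts).

The lm-backend statistics are the moderated t and F given in the README;
two-sided p-values throughout, on `d_0 + d_g` df. The nbglm backend forms
quasi-F statistics from deviance differences. The gene null model
constrains the tested coefficient to one shared value across the gene's
transcripts; it is fitted by block iteration that keeps the per-transcript
fits separable — each round refits every transcript's nuisance coefficients
with the shared value absorbed into the offset, then updates the shared
value by a damped Fisher-scoring step from the pooled per-transcript scores
(tolerance 1e-6, max 50 rounds). The transcript-level test compares the
all-equal null to the one-removed null that frees the transcript of
interest; for a two-transcript gene the one-removed null equals the full
model, so the gene and transcript tests coincide exactly. Genes with more
than 10 transcripts use a fast approximation: each transcript's coefficient
pinned at the consensus versus its own estimate. The consensus weights are
the inverse unscaled variances at convergence (expected information); the
choice between expected-information and working weights is ambiguous in
principle and this implementation uses the former consistently.

Simes gene p-values are `min_i (m p_(i) / i)` over each gene's sorted
transcript p-values. BH adjustment is applied separately at the gene level
(F and Simes columns independently) and transcriptome-wide at the
transcript level (within-gene adjustment was the alternative; transcriptome
wide matches how discovery lists are actually thresholded).

## Synthetic data

The generator works at the count level. Per gene, a zero-truncated
geometric number of transcripts (mean ~3.3, capped at 10); baseline TPMs
are heavy-tailed log-normal (meanlog 1.5, sdlog 2) normalized to 1e6 —
a parametric stand-in for an empirical abundance distribution that removes
any external-data dependency; effective lengths log-uniform on
[300, 10000] nt. Squared BCVs are scaled inverse chi-squared
(scale 0.25^2, df 40). True per-sample TPMs are gamma with squared CV
`phi_t`; expected counts follow from the library size and nucleotide
fractions; RTA is emulated by `y = tau * Poisson(mu / tau)` with `tau = 1`
with probability 0.5 and `1 + Gamma(1, 1.5)` otherwise, and resamples
redraw `tau * Poisson(y / tau)`. Counts stay fractional. Library sizes
alternate between the two configured values across samples.

Differential configurations: DTU-only genes set two transcripts' baselines
to (s/3, 2s/3) of their combined mass and swap them in group B — each
changes exactly two-fold, the gene total is conserved, and only those two
transcripts are counted as differentially used; DGE+DTU genes change one
transcript two-fold (all transcripts of the gene count as differentially
used, since every proportion shifts); DGE-only genes change all transcripts
two-fold (none count). Up/down is balanced. Defaults describe the
full-scale design (12715 genes, 4500 differential split 1500/1500/1500,
libraries 25M/100M); `SimConfig.desk_scale()` scales the gene count to 3000
(differential split proportionally) and libraries to 1M so a full pipeline
run takes seconds — these are the problem sizes used by the test suite and
the acceptance script.

What the generator does not emulate: read-level sequencing and
quantification (RTA comes from the explicit `tau`, not from annotation
topology, which is precisely what makes `tau` recovery testable), PCR
duplication, within-gene BCV correlation (real transcripts of one gene tend
to share BCV; here they are independent, which if anything disadvantages the
gene-pooled variance model), and unannotated transcripts. Passing tests
therefore demonstrate calibration and power under the stated generative
model, not under every failure mode of real libraries.

## Numerical choices and degenerate inputs

IRLS linear predictors are clamped at |eta| <= 745 (natural log), fitted
means floored at 1e-8; deviances are clipped at 0 against round-off;
a 1e-10 ridge stabilizes the information matrices; `phi < 1e-10` switches
every NB formula to its Poisson limit. Ties in ranked outputs are broken on
feature id so results are deterministic under row permutation. Transcripts
with non-positive unscaled variance are excluded from their gene with a
warning; genes reduced below two usable transcripts are dropped.
Single-transcript genes are never tested.

## Known limitations

The global `phi` is a single constant (no abundance trend); the RTA
estimator is a generic pooled quasi-Poisson statistic, not a re-derivation
of any specific quantifier-import tool; sample quality weights and random
effect blocks are out of scope for the lm backend; empirical-Bayes
moderation uses plain moment matching (the winsorized variant is available
but default-off).
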