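# Methods

This note documents the models implemented in `dotox`, the defaults they
carry, what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want to know about.

## Synthetic Diversity Outbred populations (`dotox.synthetic`)

The generator emulates a two-cohort inhalation study in Diversity Outbred
(DO) mice: 8 founder strains, outbreeding generations 7–8, balanced exposure
groups at 0/1/10/100 ppm, and micronucleated-reticulocyte (MN-RET) rates per
1,000 cells measured in blood before exposure and in blood and bone marrow
afterwards.

**Genome and map.** An abstract genome of 10 autosomes x 90 Mb with evenly
spaced markers. Positions are in Mb; no sex chromosomes and no real
recombination map. Map distance is handled through a single constant: the
expected number of founder-switch events per haplotype is
`K_TRANSITION * generation` per Mb with `K_TRANSITION = 0.00125`, i.e. about
one event per 100 Mb per haplotype in a generation-8 animal — the same order
as 0.5 cM/Mb accumulated over the outbreeding generations. The study-scale
configuration uses 90 markers per chromosome (1/Mb); desk-scale tests use
sparser maps.

**Mosaics and the switch process.** Breakpoints are a Poisson process; at
each event the founder is redrawn uniformly over all 8 (so 1/8 of events are
invisible). This makes the marginal transition over a gap of `d` Mb exactly
`(1 - r) I + (r/8) J` with `r = 1 - exp(-K_TRANSITION * generation * d)` —
the matrix exponential of the jump process — so the simulator and the HMM
share one transition model and gap kernels compose exactly.

**Founder alleles.** Biallelic markers; allele 1 is called `B`, the
heterozygote `H`, missing `N`. Outside the focal interval founders draw
allele 1 independently with probability 0.5 (partially informative markers,
as on a genotyping array). Inside the focal interval (chromosome 10,
28–36 Mb by default) one founder (`F`, CAST-like) carries allele 1 and the
other seven allele 0 at every marker — interval-private variation.

**Genotype noise.** Calls are corrupted at `error_rate = 0.002` (a wrong
symbol uniformly) and dropped to `N` at a per-sample missingness drawn from
Normal(0.053, 0.012) truncated to [0, 0.49]. Those values reproduce array
batches with mean call rate ~94.7 +/- 1.2% in which a handful of samples per
600 fall below the 90% QC bar.

**Phenotypes.** On the natural-log scale,

```
log(pre_blood)  = log(a)     + u + e
log(post_*)     = log(mu(X)) + beta * g * s(X) + u + e
```

with `mu(X) = a (c - (c-1) e^{-bX})` and defaults `a = 2.5` per 1,000,
`b = 0.018` per ppm, `c = 6` (control median ~2.5, ~5-fold induction at
100 ppm). The polygenic term `u` is multivariate normal with covariance
proportional to the ground-truth dosage kinship and is shared between pre-
and post-exposure responses; components are scaled so that
`Var(u)/(Var(u)+Var(e)) = 0.65` (the pre-exposure heritability) with total
non-QTL log variance `sigma_log^2 = 0.35^2` (a 2-log-SD control interval of
roughly 1.3–4.7 per 1,000). The QTL term uses the dominant (or additive)
coding `g` of the focal founder's true dosage, with the effect scaled by the
induced-damage fraction `s(X) = (1 - e^{-bX})/(1 - e^{-b Xmax})`: the
modifier acts on benzene-induced damage, so it is absent before exposure and
has full size at the top concentration, where its magnitude is solved to
explain ~49% of phenotypic variance. Because `u` is correlated across all
mice (average relatedness ~0.25), the population mean of `u` does not vanish
at n = 600; simulated cohort-level geometric means therefore scatter around
`a` by up to ~15% between seeds.

Raw cell counts are not simulated: the assays analyze rates per 1,000, and
counting noise from ~20,000 scored cells is small relative to `e`, into which
it is folded. `%RET` is generated as an uninformative log-normal column to
complete the table schema.

**What passing tests do not show.** The generator has constant log-scale
variance across doses, no genotype-by-environment interaction beyond the
planted `s(X)` scaling, no dose-dependent toxicity to the reticulocyte pool,
no batch effects other than missingness, and a single biallelic private
haplotype rather than 38M SNPs. Recovery of planted parameters here
demonstrates correctness of the estimators under the stated model, not
robustness to the violations real data may show (notably the variance
inflation at high dose that real MN-RET data display).

## Diplotype reconstruction (`dotox.hmm`)

A hidden Markov model over the 36 unordered founder pairs (8 homozygous +
28 heterozygous). Phase is irrelevant for dosage regression, so unordered
states halve the 64-state ordered space. Emissions: a call concordant with
the state's allele-1 copy number has probability `1 - error_rate`; each of
the two discordant symbols has `error_rate / 2`; `N` emits 1 everywhere.
Default `error_rate = 0.002`. Transitions as above; the initial distribution
is the stationary one (uniform over ordered pairs: 1/64 per homozygous
state, 2/64 per heterozygous state), which is also what an all-missing
chromosome returns, with a logged warning.

Posterior decoding (scaled forward–backward, vectorized across mice) yields
expected dosages `posterior @ counts`, which sum to 2 exactly. Brute-force
path enumeration on short chromosomes reproduces the posteriors to 1e-10.
At the study-scale map (1 marker/Mb, error 0.002, generation 8) the mean
dosage overlap with truth is ~0.99.

## Kinship, genome scan and association (`dotox.scan`)

**Kinship.** `K[i,j] = (1/m) sum_markers (d_i/2).(d_j/2)` — the Gram matrix
of founder-dosage profiles, so it is positive semidefinite by construction
(no shrinkage needed); two identical fully homozygous genomes give 1,
disjoint founder content gives 0. A single genome-wide kinship is used (no
leave-one-chromosome-out). Consequences: the null variance component absorbs
part of the focal-locus variance, so mixed-model LODs are somewhat
conservative near a strong QTL. This matches the described analysis; LOCO
could be added but is deliberately not the default.

**Mixed model and scan.** Variance components are estimated once under the
null by REML using a single eigendecomposition (the likelihood is a smooth
1-D function of h2 after rotation; grid search plus bounded refinement).
Inside the fit the kinship is rescaled to unit mean diagonal so `sigma_g2`
is the additive variance of a typical individual and h2 the per-individual
variance fraction; the likelihood is invariant to this reparameterization.
The scan whitens `y` and all designs by `(sigma_g2 K + sigma_e2 I)^{-1/2}`
and computes `LOD = (n/2) log10(RSS0/RSS1)` per marker with the 8 dosage
columns (plus covariates; cohort is included by default, switchable).
Founder coefficients are reported as deviations from their mean because the
dosage columns sum to 2. Rank deficiency is handled by least-squares
pseudo-inverse. Ties in the maximum LOD break to the lowest (chromosome,
position). `variance_explained` is `1 - RSS1/RSS0` at the peak on the
whitened scale — the quantity consistent with `VE = 1 - 10^(-2 LOD / n)`;
the unadjusted regression R^2 is also reported (`variance_explained_raw`)
and is typically larger because the founder-dosage columns soak up some
polygenic variance.

**Permutations.** Phenotype rows are shuffled jointly against genotypes,
covariates and kinship, and each permuted vector is whitened with the same
fixed transform; the kinship structure of the permuted trait is deliberately
ignored, as in standard phenotype permutation. The threshold is the
empirical (1 - alpha) quantile of the genome-wide maximum LOD over
`n_perm >= 100` permutations (default 1,000, alpha 0.05). The computation is
vectorized: per marker, one orthonormal basis projects all permuted
phenotypes at once, so 1,000 permutations over 900 markers take seconds.

**Credible interval.** `10^LOD` is normalized over the peak chromosome's
markers and mass accumulated outward from the peak, taking the heavier
neighbor first, until >= 95%; endpoints are marker positions. A flat profile
returns the whole chromosome with a warning.

**SNP association.** Within an interval, SNP dosage = `sum_f dosage_f *
allele_f` in [0, 2]; monomorphic or incomplete SNPs are skipped with a log
message; each SNP gets the same whitened regression with 1 df. When the
causal variation is private to one founder across the interval, all interval
SNPs tag the same haplotype and show near-equal LOD — association cannot
narrow the interval further, which is itself a diagnostic.

## Heritability and dominance (`dotox.quantgen`)

REML is the default for variance components (small-sample bias correction);
ML is available for likelihood-ratio work. `K ~ I` makes h2 unidentifiable
and is reported as NaN with a warning rather than an arbitrary number.

The dominance test extracts the focal founder's dosage at the peak marker,
rounds `dosage/2` to the nearest of {0, 0.5, 1} (additive coding) and sets
dominant = 1 wherever additive > 0. Additive-only, dominant-only and general
(both terms) fixed-effect linear models are fit by maximum likelihood and
compared by chi-square(1) on twice the log-likelihood difference. All three
genotype classes must be present, otherwise the general model is not
identifiable and the test refuses. The default models are plain fixed-effect
regressions without kinship — the described comparison is a simple model
contrast on one locus; with homozygous carriers rare (allele frequency 1/8
gives ~1.5% homozygotes), the power to reject additivity rests on a handful
of animals, and p-values near 0.01–0.05 at n = 150 are the expected scale.

## Benchmark concentration (`dotox.bmc`)

**Distribution.** Default log-normal: the model is fit to natural-log
responses with constant log-scale variance, and `mu(X)` is the median
response. A normal option exists for datasets whose summaries are
arithmetic. Summarized (n, mean, SD) input uses the group-sufficient-
statistic likelihood; log-normal summaries are converted by moment matching
(`s2 = ln(1 + sd^2/mean^2)`, `mu = ln(mean) - s2/2`). Individual and
summarized fits agree exactly when the summaries are sufficient.

**Fitting.** `sigma` is profiled out; (a, b, c) are optimized by multi-start
L-BFGS-B inside the box `a in (0, 10 max(mean))`, `b in (1e-6, 10]`,
`c in (1 + 1e-6, 100]`, seeded from method-of-moments values. AIC =
`-2 loglik + 2k` with k = 4. Non-convergence is a status flag, never silent.
With only 3 dose groups the 3 mean parameters saturate the group means and
(b, c) are weakly identified — expected, and the reason profile bounds
rather than Wald intervals are used.

**BMR and BMC.** `rel10`: target ratio r = 1.1. `one_sd`: r = 1 + SD0/a with
SD0 the control-group SD on the response scale (the alternative log-scale SD
definition is available via the `control_sd` argument). If `r >= c` the
status is `NA_target_exceeds_asymptote`. Otherwise the closed form above
applies and is verified against bisection to 1e-8.

**BMCL.** The model is reparameterized with BMC free (b recovered from
(a, c, BMC)); at each candidate BMC the likelihood is maximized over (a, c)
(Nelder-Mead plus L-BFGS-B, warm-started). The bound is where the profiled
deviance crosses `chi2_1(0.90) = 2.7055` (one-sided 95%), located by
geometric stepping (factor 0.8) and bisection to relative tolerance 1e-4.
Bisection is used instead of a root bracketer because the profiled deviance
carries small re-optimization jitter. Coverage of the bound over simulated
data sits in the 93–99% band.

**Lack of fit and the high-dose drop.** The fitted mean model is tested
against the saturated group-means model (same variance model) by chi-square
with df = groups - mean parameters. When the top dose misfits a saturating
model, `drop_high_dose` removes exactly the highest group (refusing if fewer
than 3 would remain) and records the action in the data's provenance — the
sanctioned remedy when the low-dose region is what matters.

**Model battery.** Exponential, Hill (Hill coefficient >= 1), linear,
quadratic and power (exponent >= 1, the restricted form) are fit under the
same distribution. Selection: among converged models with goodness-of-fit
p > 0.1, lowest AIC, with models within 2 AIC units treated as tied and ties
resolved toward the exponential (delta-AIC below 2 is not a meaningful
difference, and the exponential is the battery's reference model).

## Phenotype statistics (`dotox.phenostats`)

Counts normalize to rates per 1,000 scored cells. Group summaries are
geometric means with the antilog of (log-mean +/- 2 log-SD). The two-way
ANOVA runs on log2 values (statsmodels OLS, type-II table) with the
cohort x exposure interaction included by default; empty cells are reported
by name. Tukey HSD uses the studentized-range distribution
(scipy). Pearson correlations are computed within exposure group. Zero
rates, possible in small samples, are handled by adding half the minimum
positive value before logs, with a flag — the choice is documented here
because the upstream convention is silent on zeros.

## Problem sizes

Defaults were chosen as the smallest sizes at which each quantity is stable:
study-scale runs use 600 mice, 900 markers and 1,000 permutations;
simulation-based tests use 20 replicates for recovery checks, 200 for
calibration and coverage, and 144–300 mice per replicate depending on the
estimator. The full test suite and the acceptance script each run in a few
minutes on one CPU.

## Known limitations

* No X chromosome and no generation-specific recombination map; the
  breakpoint density constant is a documented approximation.
* Single genome-wide kinship (no LOCO) mildly shrinks LOD near strong QTL.
* The dominance test ignores kinship by default (a flagged variant adjusts).
* Constant log-variance in both the generator and the BMC likelihood; real
  MN-RET data show variance growth with dose, which is exactly the situation
  the lack-of-fit test plus high-dose drop are there to catch.
* The permutation threshold ignores relatedness under the null, which can be
  mildly liberal when heritability is high.
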