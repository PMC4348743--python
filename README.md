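# dotox

Population-based exposure-threshold estimation and genetic mapping of
genotoxicity in **Diversity Outbred (DO) mice** — a reusable implementation of
the two analytic engines behind inhalation-toxicology studies that pair
benchmark-concentration modeling of micronucleated-reticulocyte (MN-RET)
dose-response with multiparent QTL mapping of toxicity-modifier loci.

The package is aimed at quantitative toxicologists and mouse geneticists. It
ships with a synthetic DO-population generator carrying known ground truth, so
the entire analysis — genotype QC, founder-diplotype reconstruction, kinship,
genome scanning, heritability, dominance testing and benchmark-concentration
estimation — runs end to end with no external data.

## The models

**Dose-response.** MN-RET rates per 1,000 cells are log-normal; their median
follows the saturating exponential

```
mu(X) = a * (c - (c - 1) * exp(-b * X))
```

with background `a` (per 1,000), slope `b` (per ppm) and asymptote ratio
`c > 1`. The benchmark concentration for a target ratio `r` (1.1 for a 10%
relative increase, `1 + SD0/a` for a one-control-SD increase) is

```
BMC = -(1/b) * ln((c - r) / (c - 1))        (defined only when r < c)
```

and the BMCL is the one-sided 95% lower profile-likelihood bound (chi-square-1
cutoff 2.7055). When `r >= c` the benchmark response lies above the plateau
and the estimate carries an explicit NA status instead of a number.

**Genetic mapping.** Each DO genome is a mosaic of 8 founder haplotypes. A
36-state hidden Markov model (unordered founder pairs) converts biallelic
genotype calls into expected founder dosages; log MN-RET is regressed on the
8 dosage columns at each marker after whitening by the kinship mixed model
`y ~ N(Xb, sigma_g2 K + sigma_e2 I)`, giving `LOD = (n/2) log10(RSS0/RSS1)`.
Genome-wide thresholds come from 1,000 phenotype permutations, support
intervals from the Bayesian credible-interval method, heritability from the
REML variance components, and the mode of action at a locus from
likelihood-ratio tests of additive (0/0.5/1) vs dominant (0/1) allele codings.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 1   # 600 mice, 2 cohorts, 4 doses
python analysis/02_qc_reconstruct.py            # QC + diplotype HMM
python analysis/03_phenotype_statistics.py
python analysis/04_benchmark_concentration.py
python analysis/05_genome_scan.py
python analysis/06_heritability_dominance.py
```

With seed 1 this prints (abridged):

```
bone-marrow MN-RET per 1,000 (geometric mean, +/-2 log-SD interval):
   0.0 ppm: 2.46 (1.29-4.70)   ...   100.0 ppm: 11.67 (3.96-34.44)
two-way ANOVA (log2): exposure p = 2.40e-160, cohort p = 0.37
all doses (0-100 ppm):  rel10: BMC = 1.153 ppm, BMCL = 0.967 ppm
low doses (0-10 ppm):   rel10: BMC = 1.253 ppm, BMCL = 0.822 ppm
scan of 150 mice at 100 ppm: peak LOD 18.6 at chr 10 29.39 Mb (threshold 6.54)
95% credible interval: 29.4-32.3 Mb
pre-exposure blood MN-RET heritability: h2 = 0.64
general vs additive: p = 1.50e-02; general vs dominant: p = 0.08
mode of action at the locus: dominant
```

Reading the output: the MN-RET median rises ~5-fold by 100 ppm while the two
cohorts are indistinguishable; the 10%-increase benchmark concentration sits
near 1 ppm with a sub-ppm lower bound once the misbehaving top dose is
dropped; the genome scan recovers the planted protective locus on chromosome
10 (truth: 31.87 Mb, ~49% of top-dose variance) inside a ~3 Mb credible
interval; and the likelihood-ratio tests reject the additive model but retain
the dominant one — carriers of a single focal-founder allele get the full
protection.

Haplotype dosages are saved both as a long-format CSV
(`mouse,marker,founder,dosage`) and as a compact `.npz` cache holding the
`(n_mice, n_markers, 8)` dosage array plus `mouse_ids` and the marker-map
columns (`marker`, `chrom`, `pos_Mb`); `dotox.io.read_dosages_cache` reloads
it.

Programmatic use mirrors the scripts (`dotox.pipeline.run_all(RunConfig(), outdir)`
runs every stage), and each stage is importable on its own — e.g.
`dotox.bmc.fit_exponential`, `dotox.hmm.reconstruct`, `dotox.scan.linkage_scan`.

## Layout

```
src/dotox/        library: synthetic, hmm, scan, quantgen, bmc, phenostats,
                  io, config, pipeline
analysis/         numbered narrative drivers (simulate -> ... -> dominance)
tests/            pytest suite (unit, property and simulation-based checks)
scripts/          acceptance.py
docs/methods.md   model assumptions, parameter choices, limitations
```
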