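# Methods

`nipthmm` simulates targeted high-coverage cfDNA sequencing of pregnant
women and infers fetal chromosomal condition (euploidy, maternally or
paternally originated trisomy) from the simulated — or real — per-locus
counts. This note records the models, the parameter choices and their
rationale, and what the simulations do and do not establish.

## The cfDNA mixture model

Maternal plasma cfDNA is a mixture of maternal DNA (proportion `1 − FF`)
and placental/fetal DNA (proportion `FF`). At a targeted biallelic SNP,
the expected count of allele *x* is

```
mu_x = RD * [ (1 − FF) * d_m(x)/2 + FF * d_f(x)/2 ]
```

where `RD` is the mean per-locus depth, and `d_m`, `d_f` are the allele's
copy numbers in the maternal (2 copies) and fetal (2 or 3 copies)
genotypes. The fetal dosage is divided by 2 regardless of ploidy, so a
trisomic locus has expected total depth `RD * (1 + FF/2)` — the "half
extra chromosome" signal that read-count NIPT detects.

Counts are negative-binomial with a fixed variance-to-mean ratio
(`vmr = 3`), parameterised as `p = 1/vmr`, `r = mu * p / (1 − p)` so that
the mean is exactly `mu` and the variance exactly `vmr * mu`; a zero mean
short-circuits to a deterministic zero. Draws are independent across
alleles and loci. Sequencing error and missing data are not simulated:
high-coverage targeted assays observe only the designed SNP alleles, and
spurious reads are assumed to be removed upstream.

## Genetics of the simulator

Each sample draws fresh parents: two haplotypes per parent, each allele
independently the minor allele with probability `MAF` (default 0.5, the
best case for informativeness). Each parental pair undergoes one
crossover: a breakpoint uniform in `[0, n_loci]` with the suffixes
exchanged. A `crossover="subset"` switch instead exchanges an independent
random subset of positions; both readings conserve the per-locus allele
multiset, and contiguity only matters for sub-chromosomal inference,
which is out of scope. Fetal chromosome sets are then:

* euploidy — one homolog drawn uniformly from each parent;
* maternal/paternal trisomy — *both* recombined homologs of the affected
  parent plus one of the other, i.e. meiosis-I nondisjunction. No
  meiosis-II or mitotic variants are modelled.

Every sample also carries an independent euploid *reference* chromosome
with the same locus count, depth and fetal fraction — the substrate for
fetal-fraction estimation. (Its composition is a modelling choice; we
match it to the studied chromosome.)

## Informative SNPs and fetal fraction

A SNP is informative when mother and/or fetus is heterozygous. At
MAF 0.5 the informative fraction is 0.75 under euploidy and maternal MI
trisomy (`3m(1−m)` with `m = 0.5`) and 0.875 under paternal MI trisomy,
because two independent paternal alleles contribute; closed forms are in
`evaluate.theoretical_informative_fraction` and verified by simulation.

The fetal fraction estimator selects informative reference-chromosome
loci with allelic ratio `max/min > 2.5` — the mother-homozygous /
fetus-heterozygous pattern, whose expected ratio is `(2 − FF)/FF` — and
returns the median of `2*min/(max + min)`. Two deliberate details:

* the ratio filter is applied *within* informative SNPs. A
  mother-hom/fetus-hom locus has a structurally zero minor count
  (infinite ratio); letting it through would contribute 0 to the median
  and bias the estimate towards zero by a factor of ~2.
* informative loci whose minor count is drawn as 0 *are* kept (ratio
  treated as infinite, contribution 0). This keeps the estimator defined
  at very low `FF * RD` at the cost of a small downward bias, which is
  why estimation error shrinks with read depth.

For real count data without genotypes, informativeness falls back to an
observed-mode floor `min >= max(2, 0.005 * total)`, a small
absolute-plus-relative threshold that rejects pure noise without
excluding low-FF fetal signal.

## Hidden Markov models

Three HMMs classify consecutive loci; all share uniform initial
probabilities, Gaussian emissions estimated from labelled training
samples (sample mean and variance per state), and a transition matrix
built from a stay-switch ratio of 10: staying within the current fetal
condition is ten times more likely than switching condition. Moves
*between same-condition states* are not penalised — within one condition
the allelic pattern legitimately changes at nearly every informative SNP
— so the RC matrix is `[[10/11, 1/11], [1/11, 10/11]]` and a 7-state
euploid row is `(10,10,10,1,1,1,1)/34`.

* **RC** (2 states, EUP/TRI) observes per-locus total counts at all loci.
  Read counts carry no information about FF, so the deployable variant
  (`RC_fixed`) uses emissions trained at the expected median FF of 10%
  and is evaluated against samples spanning FF 1–20%; `RC_perfect`
  (emissions matched to each cell's true FF) is the upper bound.
* **AR** (7 states) observes allelic ratios of informative SNPs only, in
  chromosomal order. The states are the distinct (maternal genotype x
  fetal genotype x condition) allelic patterns `E1,E2,E3,T1,T2,T3,P1`
  (expected ratios derived by dosage enumeration; see the `hmm` module
  docstring). `P1` — mother homozygous, fetus carrying two non-maternal
  alleles — cannot arise under maternal MI trisomy and is what separates
  parental origin. State labels for training come from the simulated
  genotypes; the labelling depends only on the dosage pattern.
* **RCAR** combines both: 2-D (count, ratio) observations with diagonal
  Gaussian emissions over the same 7 states.

Emissions operate on raw (not log) allelic ratios, matching the Gaussian
approximation used throughout; a log-ratio variant would be a natural
extension but is not enabled. Informative loci whose minor count is
drawn as zero are *excluded* from AR/RCAR training and decoding
sequences: their ratio is undefined, in real data they are
indistinguishable from homozygous loci, and representing them by any
finite stand-in value systematically rewards whichever state fitted the
larger variance (measured: it drives euploid samples into the trisomy
states at low `FF * RD`, the opposite of how these models behave).
Finite ratios are still clamped at twice the 99th percentile of the
training ratios, purely to keep rare extreme ratios (minor count 1) from
inflating the fitted variances.

Decoding is exact log-space Viterbi, vectorised across samples (batched
dynamic programming with per-sample lengths; ties break to the lowest
state index). It is checked against exhaustive path enumeration on small
instances and against `hmmlearn` on shared parameters.

## Chromosome-level calling

The mode rule sums decoded state frequencies within condition groups and
calls the strict plurality; an exact tie is "unclassified", and
unclassified counts as incorrect in every accuracy figure (the metric
definition is ambiguous on this; we take the conservative reading). The
7-state trisomy group is reported as *maternal* trisomy: its patterns
occur under both origins, and maternal origin is far more common, so
this convention avoids over-calling paternal trisomy.

Two supervised meta-classifiers operate on features
`(RD, FF, state frequencies)`: a depth-3 decision tree (Gini, seed 123)
and an SVM with default parameters (RBF kernel, `C = 1`, kernel width
`1/n_features`, one-vs-one, no feature standardisation, seed 123). One
tree and one SVM per model configuration are trained on the pooled
training profiles of the whole grid — the benchmark reports single
DT/SVM columns spanning all conditions, which implies pooled training.
Features are expressed in their reporting units: RD in reads, FF and
state frequencies in *percent*. The tree is scale-invariant, but for
the unstandardised fixed-width RBF kernel the unit choice is
load-bearing: on proportion-scale features the kernel barely registers
FF/frequency differences and the SVM loses most of its low-FF trisomy
sensitivity, while percent-scale features let it localise in (FF,
frequency) space. The FF feature is the simulation truth for the
read-count models (their deployment assumes FF is externally known or
assumed) and the reference-chromosome *estimate* for AR/RCAR, which is
what those models would have in practice.

## Experiments and desk-scale defaults

The benchmark grid crosses 3 fetal conditions x FF 1–20% (step 1%) x
read depth. Desk-scale defaults keep runs tractable on one CPU: the RD
axis is thinned to the evenly spaced {1500, 4000, 6500, 9000, 11500,
14000} (the full design is 500–15,000 in steps of 500; an evenly spaced
thinning has the same mean, 7750, as the full grid, so unweighted cell
averages estimate the full-design averages without over-weighting
either end of the depth range), with 100 training and 200 test samples
per condition cell (the full design tests 10,000). Accuracy aggregates
are unweighted means over cells; fetal-fraction bands are 1–5, 6–10,
11–15 and 16–20%. At 200 samples/cell the binomial standard error of a
cell accuracy near 0.9 is ~0.02, so band and overall aggregates carry
Monte-Carlo noise of roughly +-0.01–0.03.

The targeted-loci experiment subsamples {50, 100, 200, 500, 1000} loci
per sample (uniformly, order preserved) at RD 1000 and FF 3% / 10%,
decodes with an RC model trained at each subset's own fetal fraction
(the experiment isolates the effect of locus count, not of FF
mismatch; an `emission_ff` switch restores the fixed-FF convention)
and calls with mode/tree/margin (callers trained per locus count). The
MAF experiment repeats 100
chromosomes of 1000 variants per MAF in {1, 5, 10, 20, 30, 40, 50}% and
compares observed informative fractions with the closed forms.

The experimental-data pipeline (for real targeted count tables) filters
outlier probes per (sample, chromosome) with Tukey fences at `k = 1.5`
(quartiles by linear interpolation; the multiplier is exposed because no
canonical value exists for this assay class), anchors RC emissions to
the sample's own retained reference-chromosome mean (trisomy mean
`x (1 + FF/2)`, variances `vmr x` means, assumed FF 10%), and decodes
studied loci in positional order. Absolute depths are assay-specific, so
emissions must come from the data, not from simulation.

## Numerical and degenerate-input choices

* Quartiles and percentiles use numpy's linear interpolation.
* `mu = 0` negative-binomial means yield deterministic zeros.
* Zero-coverage loci are dropped from allelic-ratio series; in
  observation matrices their ratio is defined as 1 (no information).
* Viterbi ties break to the lowest state index; the mode rule's exact
  ties yield "unclassified".
* Fewer than 4 loci: the IQR filter passes everything and logs a warning.
* RNG: every experiment derives independent per-cell streams from the
  root seed via `default_rng([seed, tags...])`, so any grid cell is
  reproducible in isolation and runs are bit-identical under a fixed
  seed.

## What the simulations do not show

The generator draws i.i.d. over-dispersed counts at independent loci
with a single shared MAF and no linkage, GC/mappability structure,
probe-efficiency variation (beyond what the IQR filter emulates in the
synthetic experimental tables), maternal CNVs, mosaicism or twin
pregnancies. Accuracies measured here therefore characterise the
*statistical* power of the models under the stated noise model, not the
performance of any particular wet-lab assay; the experimental-data
pipeline exists precisely because real probe behaviour must be anchored
per assay. Results at 200 test samples per cell estimate the large-n
design values with the Monte-Carlo tolerances stated above.
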