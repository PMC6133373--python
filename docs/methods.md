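# Methods

Statistical models, parameter conventions and numerical choices used by
`clccmap`.  Units are stated with every default; all randomness flows from
explicit integer seeds through `numpy.random.default_rng`.

## Coordinates and intervals

Genomic intervals are 1-based and inclusive at both ends internally
(`GenomicInterval(chrom, start_bp, end_bp)`, length `end − start + 1` bp).
BED files are written and read as 0-based half-open and converted at the
boundary.  `interval_length_kb` reports `round(length_bp / 1000)`, so a
1 bp interval is 0 kb.  The intersection of per-individual segment sets is
computed exactly over merged unions; outputs are maximal, disjoint and
sorted, and never extend outside any input segment.

## Genetic map

Physical distance is converted to genetic distance at a fixed 1 cM/Mb (the
genome-average convention; configurable via `cm_per_mb`) and to
recombination fractions with the Haldane map function
`θ = ½(1 − e^(−2d))`, `d` in Morgans.  No interference is modelled.

## Two-point pedigree likelihood and LOD

The likelihood treats each individual’s latent state as the phased pair of
two-locus haplotypes `((d_pat, a_pat), (d_mat, a_mat))`: `d ∈ {+, disease}`
and `a` the marker allele.  Founders take Hardy–Weinberg priors — disease
allele frequency `q` (default 1e-5) and configurable marker allele
frequencies (default equal).  A parent with phased state transmits the
disease-locus allele of one chromosome with probability ½, and the marker
allele of the same chromosome with probability `1 − θ` (the other with
`θ`).  Penetrance is `(0, 0, 1)` by default (fully penetrant recessive, no
phenocopies); observed marker genotypes enter as indicators over unordered
allele pairs, `-1` meaning missing.

The sum over all latent states is computed *exactly* by discrete variable
elimination (sum–product) with a greedy smallest-table ordering.
Consanguinity loops need no special casing — they simply yield larger
intermediate factors.  Each elimination rescales its table by its maximum
and accrues the log, so likelihoods near the underflow limit (e.g. with
`q = 1e-5` and several obligate carriers) remain accurate; the result is
returned in natural log, `−inf` when the genotypes are
Mendelian-inconsistent.  Pedigrees are capped at 14 individuals (the exact
computation remains sub-second there; the cap is a guard, not an
algorithmic limit).  The test suite validates the implementation against
an independent full joint enumeration (depth-first search over every
individual’s state) to 1e-12 relative error.

`two_point_lod` evaluates `LOD(θ) = log10 L(θ) − log10 L(½)` per family on
a θ grid (default `{0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5}`), sums across
independent families, and reports the maximising θ (ties to the smallest).
`LOD(½) = 0` identically; an obligate recombinant forces `LOD(0) = −inf`.
A family whose genotypes are impossible at *every* θ raises an error
naming the family.

## ROH detection and interval refinement

`detect_roh` scans each individual’s genotypes left to right, growing a
window while its heterozygote and missing-call counts stay within budget,
trimming both boundaries to homozygous SNPs, and emitting maximal
non-overlapping segments that meet both a SNP-count and a physical-length
threshold.  Defaults: ≥ 25 SNPs, ≥ 500 kb, 0 heterozygotes, ≤ 2 missing.
On error-free data, planted homozygous blocks are recovered with zero
boundary error; thresholds guarantee no false segments shorter than the
minima.

`shared_autozygous_interval` intersects the per-affected ROH sets (all
individuals required by default).  `refine_by_haplotype` then returns the
longest run of consecutive SNPs at which *every* affected individual is
homozygous for the *same* allele — the shared founder haplotype — with
ties broken to the leftmost run, or `None` if no such SNP exists.

## EM haplotype frequencies and the founder-sharing statistic

`em_haplotype_frequencies` implements Excoffier–Slatkin-style EM over
unphased multi-SNP genotypes.  E-step: each individual is distributed over
its compatible unordered haplotype pairs proportionally to `f_h · f_h'`
(doubled for heterozygous pairs); missing sites are summed over by
expanding all consistent alleles.  M-step: expected haplotype counts are
renormalised.  Iteration stops when `max |Δf| < 1e-8` or at 1000
iterations; the log-likelihood trace is non-decreasing.  Initialisation is
the product of observed per-site allele frequencies; seeded Dirichlet
random restarts are available (best final log-likelihood wins).  An
individual with zero compatible haplotypes raises an error naming it.

`founder_sharing_probability(f, k) = f^k` is the probability that `k`
independent chromosomes all carry a haplotype of population frequency `f`
by chance.  At `f = 0.03`, `k = 7`: `2.187e-11` (reported to one
significant figure as 2e-11).  It is non-increasing in `k` and
non-decreasing in `f`.

## Variant filtering

`filter_candidate_variants` reads annotated VCF v4.x records (cyvcf2) and
keeps those that (a) lie inside the critical interval (1-based inclusive
at both boundaries), (b) carry a consequence in the configured
non-synonymous set (missense, stop gained/lost, frameshift, splice
donor/acceptor, start lost, in-frame indels), (c) have population AF ≤ the
threshold (default 0.01; missing AF passes), and (d) are homozygous
alternate in every proband (default: all affected members with genotypes).
Each surviving record gets a cosegregation verdict over the *whole*
pedigree: it fails if any affected member is not hom-alt or any unaffected
member is hom-alt, and the failing individuals are listed.  Records
missing the consequence annotation are counted, logged and skipped rather
than aborting the run.

## ERG spectral model

The cone-driven ERG amplitude at irradiance `I` (hν·µm⁻²·s⁻¹) and
wavelength λ (nm) is modelled as a sum of four spectrally weighted Hill
saturation functions:

```
V(I, λ) = Σ_c  V_c · Iⁿ / (Iⁿ + K_cⁿ) · A_c(λ),   c ∈ {UV, blue, green, red}
```

with amplitude maxima `V_c` (µV), half-saturation irradiances `K_c` and
Hill exponent `n = 1` by default (the classical Naka–Rushton/Michaelis
form; the printed equation does not state an exponent, and `n` is
configurable).  `A_c(λ)` are peak-normalised pigment absorbance templates:
the Govardovskii et al. (2000) A1 alpha-band template by default
(normalised at λ_max, which matches the numeric maximum to < 0.1%), or a
log-normal alternative (σ = 0.07).  Default λ_max: 362 (UV), 415 (blue),
480 (green), 570 (red) nm; template support is 300–700 nm.

Fitting (`fit_cone_components`) is bounded multi-start nonlinear least
squares (scipy `least_squares`, trust-region reflective): `V_c ≥ 0`,
`K_c` optimised as log10 within [0, 8].  16 seeded starts by default; the
best by SSE wins (ties to the smallest ΣV_c).  At least 8 distinct
(wavelength, irradiance) cells are required — the parameter count; an
all-zero dataset returns `V_c = 0` with a warning.

Constant-quanta sensitivity spectra use `S(λ) = V(Q₀, λ)/Q₀`, reported in
nV per quantum (µV→nV factor 1000) at `Q₀ = 2500 hν·µm⁻²·s⁻¹`.
Empirical spectra average per-eye replicate means at the irradiance
closest to Q₀, with SEM = sd/√n across eyes.  `group_depression` reports
the percent reduction of a mutant spectrum relative to wild type, both at
the wild-type peak and averaged over wavelengths where the wild-type
sensitivity exceeds 5% of its maximum (guarding against division by tiny
values).

The default simulation grid mirrors the experimental design: 9 wavelengths
(350–630 nm, 35 nm steps) × 7 irradiances (four log decades around Q₀,
`2500·10^((k−3)·2/3)`, k = 0..6) × 4 replicate eyes, with additive
Gaussian noise of SD `0.5 µV + 5% · |amplitude|`.  Under this design the
fit recovers `V_c` within 15%, `K_c` within a factor 1.5, spectra within
10% relative RMS, and a 60% simulated depression as 60 ± 5%.

## Group statistics

`unpaired_t_test` implements the pooled-variance Student t test (default)
and the Welch variant; degenerate inputs return defined values with
warnings (n < 2 or zero variance with equal means → t = 0, p = 1; zero
variance with unequal means → p = 0 sentinel).  `ratio_of_means` divides
group means and rounds to 3 decimals — dividing published morphant means
0.019/0.13 mm² gives 0.146, which differs from a published per-animal
ratio convention; `mean_of_ratios` implements the per-subject alternative,
and both are reported because printed group means need not be
arithmetically consistent with printed per-group ratios.
`rescue_fraction` reports the percent of embryos labelled "normal" to one
decimal.

## Synthetic-data generators

**Pedigrees.** Templates: `nuclear`, `first_cousin`,
`double_first_cousin`, `custom`.  Affected/unaffected individuals are
always children of the final mating (a recessive model gives an affected
founder no within-pedigree explanation, so that is rejected).  Seeds only
randomise child sexes.

**Marker maps.** Array-density biallelic SNPs: 5 kb spacing over 5 Mb
(1,000 markers) by default, MAF ~ Uniform(0.1, 0.5); anchor positions can
pin markers to exact printed coordinates so simulated intervals can be
bounded by them.

**Gene drop.** Founder chromosomes carry per-locus origin labels; a
planted founder haplotype (label −1 inside the planted region, carrying
the disease allele at the region midpoint by default) is placed in one
copy in a shared founder ancestor when one exists (consanguineous
templates) or one copy per parental lineage (nuclear families, modelling
an unrepresented common ancestor).  Meioses follow the Haldane model via
independent inter-locus crossover indicators.  Rejection sampling
conditions on the affection pattern (affected ⇔ disease-homozygous) and,
by default, on every affected individual's autozygous segment covering the
whole planted region; exceeding the attempt budget raises an explicit
error.  The truth object records genotypes, disease genotypes, origin
labels, the realised IBD segments and the attempt count.  Gene-dropped
genotypes always pass an independent Mendelian-consistency check, and
empirical recombination fractions over ≥ 10⁴ meioses match the configured
map distance within 3 binomial SE.

**Control cohorts.** `simulate_cohort_chromosomes` draws each chromosome
as the founder haplotype with probability `f` and otherwise as a
linkage-equilibrium background *conditioned on differing from the founder
haplotype in at least one SNP*, so the true population frequency of the
haplotype is exactly `f` (unconditioned backgrounds would inflate it by
chance matches).

**Morphometry.** Group means, units and sample sizes follow the published
knockdown-versus-control comparison; the unpublished SDs are set so the
two-sample t statistics land near the published p-values.  A zero-SD group
yields exactly its mean.

## Pipeline

`run_pipeline` executes simulate → roh → lod → founder → variants → erg →
stats from a single YAML config validated by pydantic (unknown keys
rejected; errors reported exhaustively with paths).  A single master seed
fans out per stage via `SeedSequence((master_seed, stage_index, extra))`,
reduced mod 2³¹, so stages can be re-run in isolation reproducibly.  Notes
on stage behaviour:

* **lod** uses the simulated disease variant itself as the marker — the
  "two-point LOD at the variant" convention — because a random nearby
  background SNP may be uninformative if the founder haplotype happens to
  carry its major allele.
* **roh** maps in consanguineous families only (falling back to all
  families when none are): outbred affecteds are homozygous only across
  the planted block, below the 500 kb ROH threshold, and contribute no
  callable ROH — matching standard homozygosity-mapping practice.
* **founder** estimates the planted haplotype's frequency over 8 evenly
  spaced region SNPs from a simulated 200-individual control cohort, then
  reports `f̂^k`.
* Machine outputs (PED/MAP/BED/TSV/JSON) go to the output directory;
  logging goes to standard error with stage timers; the report exists as
  JSON and as human-readable text, with provenance (seed, config SHA-256,
  package version).  Reruns with an identical config are byte-identical
  up to wall-clock timings.

## Deliberate scope limits

No multipoint linkage, liability classes or phenocopies; no IBD HMMs or
phasing beyond EM frequency estimation; no sequence-level simulation; no
consequence prediction (annotations are read, not computed); no
time-domain ERG waveform modelling; no multiple-testing correction.
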