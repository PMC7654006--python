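# Methods

This note documents the models, parameter choices and numerical conventions
behind `imputebench`, and what the synthetic benchmarks do and do not show
about real data.

## Evaluation framework

### Empirical accuracy metrics

Metrics are computed per marker over an explicit set of evaluated samples
(supporting designs where only a base subset of a jointly phased target panel
is scored). R²dose and R²gt are squared Pearson correlations computed with the
two-pass mean-centred formula; a constant vector on either side yields NA,
never 0, so that "the marker was imputed to the major allele in everyone" is
distinguishable from "the marker was imputed badly". The concordance rate is
always defined. These conventions interact: a rare marker lost by imputation
has CR ≈ 1 and R² = NA, which is precisely why CR alone overstates rare-variant
accuracy and why the density accounting below exists.

NA propagation is uniform everywhere: bin means and correlations drop NA values
pairwise and report the contributing marker counts, so nothing shrinks
silently.

### Model-based quality score

The per-marker Rsq estimator is the dosage-variance ratio used by the
MaCH/minimac family: Rsq = Var(d) / (2 p̂ (1 − p̂)) with p̂ = mean(d)/2,
population variance (divide by N), clipped to [0, 1], NA when p̂ ∈ {0, 1}, and
exactly 0 for a constant dosage vector (computed directly rather than through
the variance, to avoid returning rounding residue). The diploid form is the
default because unphased dosages are what evaluation pipelines usually see; a
haploid variant (denominator p̂(1 − p̂)) is provided for phased allele dosages.
Hard-called dosages without heterozygotes give Var(d) = 4p̂(1 − p̂), so the
ratio saturates at the clip boundary — a reminder that Rsq is an estimator of
imputation information, not a correlation.

### MAF stratification

Bins are left-closed over (0, 0.5]: rare [0, 2%), low-frequency [2%, 5%),
common [5%, 50%], with a two-class variant (below/above 5%) for compact tables.
MAF for binning comes from the true genotypes of the evaluated samples;
reference-panel MAF is available by building the table against the reference
instead. Markers with MAF = 0 in the evaluated samples belong to no bin but are
counted in the global row. Per-bin means weight markers equally within a
replicate and are then averaged across replicates.

### Quality control

Filter order is fixed and logged: (1) unmapped/non-autosomal markers, (2)
samples with call rate < 95%, (3) markers with call rate < 95%, (4) mode-fill
of remaining sporadic missing genotypes (ties break toward the smaller
genotype), (5) Hardy-Weinberg exact test at p < 1e-5, (6) optional MAF floor.
Filling before the count-based marker filters makes a second QC pass a strict
no-op (idempotence), which would not hold with fill-last because filling
changes the genotype counts that the HWE test sees. The HWE test is the
two-sided exact test on the hypergeometric null (probabilities built by the
stable recurrence from the modal heterozygote count, summing outcomes no more
probable than the observed one, with a 1e-10 relative tie tolerance). Mode
filling is a deliberately simple stand-in for model-based refill of sporadic
missing genotypes; it touches at most 5% of cells per marker by construction
and is flagged in the QC log.

### Misplaced-SNP scan

Autosomes are partitioned into fixed segments of 100 kb anchored at position 0,
half-open, indexed by `pos // width` on 1-based positions. A SNP is poorly
imputed iff MAF > 1% and R²dose < 0.8; NA R²dose never counts as poor (the
marker still counts toward segment size). A segment is flagged iff it has
strictly more than three poorly imputed SNPs, and every SNP in a flagged
segment is reported as putatively misplaced. Both thresholds, the width and
the MAF floor are parameters.

### Density accounting and assembly comparison

Polymorphism is judged on discrete genotypes (best-guess for imputed data): a
fractional dosage at a monomorphic marker does not make it polymorphic.
Summary counts are taken among markers polymorphic in the reference panel and
satisfy two internal identities that the tests enforce: target-polymorphic plus
target-monomorphic equals reference-polymorphic, and falsely-imputed markers
are a subset of target-monomorphic ones. Assembly comparison joins two maps on
marker id and partitions markers into same-chromosome, chromosome-changed,
newly-mapped, lost, and unmapped-in-both, carrying mean R²dose under each map
for markers where both are defined.

## Synthetic data

### Population model

Founder haplotypes carry alleles drawn i.i.d. per marker from a Beta(0.4, 0.4)
frequency spectrum truncated to [0.005, 0.995] — a U-shaped, rare-variant-heavy
spectrum resembling array content after ascertainment at both tails. The
population then drifts for `mosaic_generations` generations: each generation
draws every haplotype from two parents in the previous pool with crossovers at
`recomb_rate_per_bp` (default 1e-8 per meiosis), chromosomes assorting
independently. Defaults: 300 founder haplotypes, a breeding pool of 1500
haplotypes, 400 generations, 3000 markers on two 5-Mb chromosomes, 400 diploid
samples. With these values haplotype segments shared with the founders average
roughly 250 kb, so LD decays well inside a chromosome, and the pool is large
enough that sampled individuals are not all close relatives — without that, a
deliberately misplaced marker is still imputed correctly because the template
matched at the wrong locus is a genome-wide relative that also matches at the
true locus, and misplacement detection becomes meaningless. The breeding pool
is the knob trading relatedness against runtime.

What the simulator does **not** model: explicit demography or effective
population size, mutation, genotyping error in the reference, pedigree
structure, and chromosome-count realism (two chromosomes by default; up to 29
autosomes are configurable). Passing benchmarks on this generator therefore
demonstrates correctness of the evaluation machinery and qualitative behaviour
of haplotype-copying imputation, not calibrated accuracy values for any real
breed.

### Stand-in imputer

`ls_impute` runs a forward-backward pass per target haplotype over K reference
haplotype states with uniform-jump transitions: switch probability
s = 1 − exp(−ρ·d/K) between adjacent markers at distance d (reset to uniform at
chromosome boundaries) and emission 1 − ε / ε at typed sites. Defaults
ε = 1e-3 and ρ = 1.5e-3 per bp; ρ was calibrated once so that the expected
number of template switches per chromosome matches the simulator's effective
mosaic rate for mid-sized panels, and accuracy is insensitive to it within an
order of magnitude. Posteriors are normalised per site (scaled forward
algorithm); the forward matrix is stored in float32 and targets are processed
in chunks sized to keep it around a quarter gigabyte. Dosage at every marker is
the posterior-weighted reference allele summed over the sample's two
haplotypes, clipped to [0, 2]; best-guess is the rounded dosage; the reported
per-marker Rsq is the estimator above applied to the imputed dosages.

Target phase is taken from the simulator (true haplotypes); statistical phasing
is out of scope. Its imperfection is emulated by `inject_switch_errors`, which
swaps a sample's two haplotypes from random switch points onward (genotypes are
invariant under this corruption — only haplotype context degrades, which is
exactly how phasing errors hurt imputation, and it hurts rare alleles most
because a broken context makes their carrier haplotypes unrecognisable). The
standard study conditions apply a baseline switch rate of 0.008 per marker;
the target-panel-size design replaces it with `phase_error_scale / n_total`,
so larger jointly phased cohorts behave like better-phased ones. This is an
emulation of the real mechanism (phasing quality improves with cohort size),
not a mechanistic reproduction.

### Corruption fixtures

`inject_misplacement` relocates compact blocks of markers (contiguous within a
caller-supplied candidate set, e.g. common non-typed markers) to random loci,
with destinations on the origin chromosome required to lie at least 1 Mb away:
shifts inside the LD range barely perturb imputation and are not the failure
mode the scanner targets. `make_assembly_pair` derives two maps that differ by
a requested number of unplaced and chromosome-reassigned markers, giving exact
ground truth for the comparison machinery.

## Benchmark study conditions

The acceptance benchmarks (tests and `scripts/acceptance.py`) run at fixed,
documented scales chosen to finish in about a minute on one CPU while leaving
the qualitative effects clearly resolved:

- **Reference-panel sweep**: 300 samples, 6000 markers, reference sizes
  25/50/100/200, 100 evaluated targets, 3 replicate splits, every 10th marker
  typed, baseline phase-error rate 0.008. Mean R²dose rises strictly with
  reference size and low-frequency markers trail common ones at every size;
  the correlation between Rsq and the empirical metrics rises with reference
  size.
- **Misplacement scan**: 280 samples, 3000 markers, eight blocks of ten common
  markers relocated, reference 200, 60 targets, every 5th marker typed,
  phase-error rate 0.002 (the scan is performed on the best-imputed
  configuration). A block counts as detected when the majority of its markers
  are flagged; the false-flag rate is measured over segments containing no
  relocated marker.
- **Noise-imputer calibration**: 200 markers × 500 samples per error rate.
- **HWE agreement**: exhaustive over all genotype configurations up to 50
  individuals (tests) / 30 (acceptance script).

## Numerical conventions and degenerate inputs

1-based marker positions internally (VCF convention), 0-based half-open BED on
export. Dosages read from files may exceed [0, 2] by at most 1e-6 (clipped,
counted, reported); larger violations are errors. Tables are written with
`%.17g` floats and `NA` for missing, making write/read round-trips lossless and
repeated runs byte-identical. All randomness flows through
`numpy.random.SeedSequence` with documented substreams: per-replicate sub-seeds
derive from (master seed, replicate index), and the simulator uses separate
streams for positions, frequencies, founders and descent, so each component is
reproducible in isolation. Degenerate inputs fail loudly: empty panels after
QC, reference panels of fewer than two haplotypes, empty marker intersections
and misaligned marker lists all raise rather than degrade.

## Known limitations

The imputer is exact but naive (O(markers × reference haplotypes) per target
haplotype); it is meant for benchmark-scale data, not production cohorts. The
model-based Rsq of blended posteriors runs lower than that of a production
imputer with well-matched templates, so its absolute level should not be
compared against published values — its correlation structure with the
empirical metrics is the meaningful output. CR's inflation, the NA conventions
and the density identities are exact properties and transfer to real data;
absolute accuracy values do not.
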