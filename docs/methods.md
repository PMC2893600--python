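# Methods

`xmask` implements an RNA-based protocol for reanalyzing cross-species
hybridization (CSH) microarray data: transcript profiling of a *target*
species on a high-density oligonucleotide array designed for a closely
related *reference* species. Sequence divergence biases such data in two
ways — probes overlapping inter-species variable (ISV) transcript regions
hybridize poorly (lost sensitivity), and their residual signal distorts
fold-change estimates (lost accuracy). Between two target genotypes,
single-feature polymorphisms (SFPs) add genotype-specific probe artifacts
that masquerade as differential expression. The pipeline removes both
classes of biased probes before summarization.

## The masking rule

Probe-level intensities are background-corrected (normexp convolution,
posterior-mean signal) and quantile-normalized across all arrays. For a
signal intensity threshold *t*, a probe is **kept** iff it reaches *t* in at
least *R* of the *Ts* arrays, where *R* is the number of replicates per
sample type; otherwise it is masked for all samples. Equivalently, a probe
is masked when it falls below *t* in at least `ceil(P·Ts) = Ts − R + 1`
arrays with the defined percentage

    P = (Ts − R + 1) / Ts,

reported to two decimals. For the bundled balanced design — two genotypes ×
two stem tissues (elongating, ES, and post-elongation, PES) × three
replicates, so Ts = 12, R = 3, S = 4 sample types — P = 0.83: a probe
survives only if at least one sample type shows it consistently above
threshold. The boundary comparison is inclusive (at/above counts as above).
Masks are built at a series of intensity points (default
5, 7, 10, 15, 20, 30, 40, 60, 80, 100, 120, 160, 320, 640, 1280, 2560) and
are nested by construction. The SFP mask is a plain probe list supplied by
the user (such lists are produced by genotype-comparison studies upstream);
the union of an ISV mask and the SFP mask is the *double mask*.

## Summarization

Retained probes are summarized per probe set by Tukey median polish on
log2 intensities (row sweeps then column sweeps, at most 10 iterations,
relative tolerance 0.01 on the total absolute residual — the classic
`medpolish` stopping rule). The expression index of a sample is
`overall + sample effect`, the standard PM-only RMA summary. Probe sets
retaining fewer than `min_probes` probes (default 1) are dropped and
counted in the log. Internally, probe sets with the same retained-probe
count are polished as one vectorized stack with per-set convergence
tracking; results are identical to polishing each table alone (tested
against a plain-loop reference).

## Threshold selection

The operating threshold is chosen by comparing the target species' PES/ES
expression contrast against the same contrast measured in the reference
species (computed once, unmasked), under the assumption that the tissue
contrast is largely conserved between the two species. For each threshold:

* **sensitivity** — the number of *commonly-selected* genes, those with at
  least a 2-fold PES-vs-ES difference in both species. Direction is not
  required to agree by default (`concordant=True` for the stricter rule).
* **accuracy** — the Pearson correlation of the two species' log2(PES/ES)
  values over the commonly-selected genes (undefined below 3 genes).

Both curves are min-max scaled over the threshold series and the threshold
maximizing the smaller of the two scaled values is picked (ties go to the
smaller threshold). This maximin rule formalizes "the point where the
rising accuracy curve and the falling sensitivity curve intersect" without
relying on dual-axis geometry. Its resolution is about one octave: on
grids finer than roughly ×2 spacing, neighboring thresholds differ by less
than the sampling noise of the two curves, so recovery experiments use the
octave subgrid 5, 10, 20, 40, 80, 160, 320, 640.

## Differential expression

Genotype contrasts within one tissue use a two-sample pooled-variance
t-test per probe set (Welch optional; arrays with n = 3 per group were
classically analyzed with the equal-variance test), Benjamini–Hochberg FDR
across all tested probe sets, and a fold cutoff. Defaults: p < 0.001,
FDR < 0.05, ≥2-fold. Probe sets with zero variance and equal means in both
groups get t = 0, p = 1. Control probe sets (e.g. a microsymbiont's) can be
excluded by id regex before testing so they do not enter the FDR. The
three-way comparison of DE sets (no mask / ISV mask / double mask) labels
`none − double` as putative false positives from ISV and/or SFP probes,
`ISV − double` as putative false positives from SFPs, and
`double − (none ∪ ISV)` as putative false negatives, alongside the full
Venn region counts.

## Genome clustering test

DE genes mapped to single loci (top hit only; duplicate probe-set rows are
dropped with a warning) are profiled in sliding windows (default 50 kb
shifted by 10 kb; half-open intervals, 0-based coordinates) and tested for
chromosomal clustering by Monte Carlo bin occupancy: the genome is cut into
non-overlapping windows (`ceil(length/W)` bins per chromosome, last bin
truncated), and the observed number of bins holding exactly *k* genes is
compared with its null distribution over repeated random placements of the
same number of genes (default 2000 repetitions; SD uses the n−1
denominator). `z = (observed − mean)/SD`, reported to one decimal;
|z| ≥ 2 flags clustering at occupancy *k*. The default null places genes
iid-uniformly on the concatenated genome; `permute_loci` instead samples
without replacement from a supplied locus universe and is the more
conservative choice when gene density is non-uniform. Occupancy classes the
null never produced, or with zero SD and a different observation, are
flagged as undefined rather than reported as infinite.

## The synthetic data generator

`xmask.simulate` draws probe-level datasets with complete ground truth.
Probe log2 signal is additive — per-gene baseline N(8, 1.5²), per-probe
affinity N(0, 0.8²), per-gene tissue effects (15% of genes,
|effect| ≥ 1, magnitude from a truncated N(0, 1.5²)), genotype effects in
the target species (5% of genes, |log2| uniform in [1, 3]) — with
lognormal replicate noise (σ = 0.3). The reference species shares tissue
effects at correlation ρ = 0.9 and draws its own probe affinities.

Four further mechanisms make the generator reproduce the biases the
pipeline exists to remove; without them a constant log2 attenuation is
absorbed into median-polish probe effects and masking would change
nothing:

* **Additive hybridization background.** Observed intensity is
  `2^log2signal + B` with `B ~ N(100, 20²)` clipped at zero — the same
  convolution structure normexp assumes. Probes whose specific signal sits
  near or below this floor report fold changes compressed toward 1.
* **Clustered divergence.** Each gene draws a divergence propensity from a
  Beta distribution (mean = the ISV probe fraction 0.25, concentration
  2.0) and its probes are ISV at that rate, so a diverged minority of
  genes has most of its probes affected — the regime in which a robust
  median-based summary is actually captured by the biased majority.
* **Coherent cross-hybridization.** All ISV probes of a gene additionally
  bind one random unrelated transcript (attenuated by the same
  δ_ISV = 3), making their ratios mixtures of two genes' patterns —
  confidently wrong rather than merely shrunk.
* **Probe×tissue response wobble.** Each probe has a N(0, 0.3²) log2
  response offset per tissue, constant across replicates and genotypes and
  independent between species. It cancels in genotype contrasts but makes
  summaries built from very few probes systematically less reliable — the
  reason masking *too* aggressively costs accuracy.

SFP probes (200 by default, δ_SFP = 2.5 in one genotype) are planted in
runs of 9 of a probe set's 11 probes, on genes expressed above the
baseline mean and free of true genotype effects: one polymorphic probe of
eleven cannot move a median polish, and real SFP lists — themselves called
from hybridization intensities — are biased toward expressed genes. Loci
are placed uniformly on a configurable genome (default eight chromosomes
totalling ~266 Mb, a compact legume scale); `plant_cluster` repositions
chosen genes into a window for clustering-recovery experiments. With
`noise_sd = 0` all stochastic measurement components (noise, background
variability, wobble) are off and output is a deterministic function of the
planted effects.

### What the generator does and does not emulate

It reproduces the qualitative CSH phenomenology: probe and probe-set
retention fall (rapidly and slowly, respectively) with threshold; the
commonly-selected gene count rises to an interior peak and then falls; the
cross-species ratio correlation improves with moderate masking and
degrades under aggressive masking; SFP artifacts create false-positive DE
calls that double-masking removes; low-abundance transcripts remain
undetectable. It does not emulate spatial chip artifacts, MM probes,
scanner saturation, sequence-dependent affinity (affinities are iid), or
realistic correlation between divergence and expression level; passing
tests therefore validate the pipeline's logic and its response to these
bias mechanisms, not performance on any particular real array.

## Numerical and design choices

* Quantile normalization ties receive the mean of the quantile values they
  span; the transform is idempotent on tie-free data.
* normexp parameters are mode-based: background mean at the (refined)
  smoothed-histogram density mode, normal SD from the sub-mode spread
  (doubled by symmetry), exponential rate from the mean above-mode excess.
  The posterior mean is evaluated in log space and is stable far below
  background.
* Masking thresholds apply to background-corrected, quantile-normalized
  intensities (the pipeline's default order); `--bg none` applies them to
  normalized raw intensities instead.
* The reference-species expression used for threshold selection is always
  computed unmasked.
* Probe sets losing all probes are dropped, not NA-filled.
* A single CLI seed fans out to stages by fixed offsets, so any stage can
  be re-run in isolation and reproduces its output byte-identically.

### Recovery-experiment designs (fixed in the test suite)

* *Threshold recovery* uses a calibration dataset with baseline SD tightened
  to 0.75 (4000 probe sets): with the default spread of 1.5 the attenuated
  probe cloud overlaps the dim tail of clean genes and no threshold
  separates them — an identifiability limit of the data, not of the picker.
  The planted level is defined per seed as the grid threshold maximizing
  the Youden separation (fraction of ISV probes masked minus fraction of
  clean probes masked); the picked threshold must land within one octave
  grid step in ≥80% of 20 seeds.
* *Masking-benefit* assertions (strict gain in planted-DE detection and in
  cross-species correlation) are evaluated at the fixed operating threshold
  40, inside the planted zone, in every one of 10 seeds; the picked
  threshold must additionally never do worse than no masking.
* *Cluster recovery* plants 4 genes in one 50 kb bin among 1400 uniform
  loci on a 2 Gb, 8-chromosome genome (a large-crop scale chosen so the
  null occupancy spectrum at k = 4 is resolvable with 2000 repetitions while
  background collisions with the planted bin stay rare) and requires
  |z| ≥ 2 at some k ≥ 3 in ≥90% of 20 seeds.
* The end-to-end detection benchmark scores recall over genes detectable on
  the array (noise-free truth signal above log2 of the background mean in
  the weaker genotype); transcripts below the hybridization floor are
  unmeasurable by construction — the protocol is inherently biased toward
  abundant transcripts.

## Known limitations

* The maximin threshold picker has ~one-octave resolution; on fine grids
  neighboring picks are statistically indistinguishable.
* The masking protocol cannot rescue genes whose expression sits at the
  background floor, and heavily diverged genes that lose all probes are
  dropped rather than recovered.
* Chip-geometry (x, y) mask addressing is not modeled; probes are addressed
  by identifier.
* P = (Ts − R + 1)/Ts reproduces the balanced-design behavior ("kept iff at
  least R samples reach the threshold"); unbalanced designs are rejected by
  validation rather than given a generalized P.
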