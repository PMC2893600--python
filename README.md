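# xmask

Probe masking and reanalysis for cross-species microarray hybridization
(CSH) — transcript profiling of one species on a high-density
oligonucleotide array designed for a close relative.

Sequence divergence between the two species biases CSH data twice over:
probes overlapping inter-species variable (ISV) transcript regions
hybridize poorly, lowering the number of expressed genes detected
(*sensitivity*), and their residual near-background signal distorts
fold-change estimates (*accuracy*). When two genotypes of the target
species are compared, single-feature polymorphisms (SFPs) add
genotype-specific probe artifacts that masquerade as differential
expression. `xmask` implements an RNA-based protocol that removes both
probe classes before summarization, for users (plant and animal
transcriptomics groups working on species without their own array) who
need CSH data they can trust without any genomic-DNA hybridization or
prerequisite sequence information.

## Method in brief

Probe intensities are background-corrected (normexp posterior mean) and
quantile-normalized. At a signal threshold *t*, a probe is kept iff it
reaches *t* in at least *R* of the *Ts* arrays (R = replicates per sample
type); equivalently it is masked when below *t* in ≥ ceil(P·Ts) arrays,
with the defined percentage

    P = (Ts − R + 1) / Ts        (= 0.83 for the 2×2×3 design, Ts = 12, R = 3)

A mask series is built over a grid of intensity points; retained probes
are summarized per probe set by Tukey median polish (PM-only RMA). The
operating threshold maximizes min(scaled sensitivity, scaled accuracy),
where sensitivity counts *commonly-selected* genes (≥2-fold tissue
contrast in both species) and accuracy is the Pearson r of the two
species' log2 tissue ratios over those genes. Differential expression
between genotypes uses a pooled-variance t-test with
Benjamini–Hochberg FDR (p < 0.001, FDR < 0.05, ≥2-fold), with ISV and
ISV+SFP ("double") masking compared by Venn logic to estimate putative
false positives/negatives. Mapped DE genes are tested for chromosomal
clustering by Monte Carlo bin occupancy
(z = (observed − null mean)/null SD per occupancy class, |z| ≥ 2
significant). A bundled generator produces synthetic two-species datasets
with planted ISV/SFP probes and DE truth, so the whole pipeline is
testable offline. See `docs/methods.md` for the full model.

## Worked example

```
$ printf 'n_probesets: 2000\n' > sim.yaml
$ xmask simulate --config sim.yaml --seed 1 --out-dir sim
$ xmask pipeline --sim-dir sim --out-dir run --seed 1 \
      --thresholds 5,10,20,40,80,160,320,640
pipeline complete; picked threshold 320
```

`run/curve.tsv` holds the threshold evaluation:

```
threshold  n_probes_retained  n_probesets_retained  n_common_genes  pearson_r
      5.0              22000                  2000             164   0.946725
     10.0              22000                  2000             164   0.946725
     20.0              22000                  2000             164   0.946725
     40.0              19476                  1987             180   0.947268
     80.0              15394                  1910             186   0.951411
    160.0              11966                  1758             184   0.949806
    320.0               8239                  1475             167   0.953320
    640.0               4845                  1068             132   0.957865
```

Probes drop fast with threshold while probe sets drop slowly; the number
of commonly-selected genes rises from 164 to a peak of 186 at threshold 80
as compressed ratios of diverged genes are restored, then falls as
informative probes are lost, while the cross-species correlation climbs
from 0.947 toward 0.958. The maximin rule picked 320 here, trading some
sensitivity for accuracy; thresholds 80–320 are nearly equivalent by its
score. `run/manifest.yaml` records the genotype contrasts under the three
mask conditions:

```
de: {none_PES: 96, isv_PES: 94, double_PES: 78, ...}
compare_PES:
  putative_fp_isv_sfp: 28   # called unmasked but not after double-masking
  putative_fp_sfp: 16       # called with ISV mask only, gone after SFP mask
  putative_fn: 0
```

Of 96 PES-tissue DE calls made without masking, 28 disappear after
double-masking — putative false positives from ISV and/or SFP probes — and
16 of the ISV-masked calls vanish once SFP probes are also removed
(the generator plants its SFP artifacts on genes with no true genotype
effect, so these are genuine artifacts being caught). Mapping the 78
double-masked DE genes and testing for clustering:

```
$ xmask cluster --loci de_loci.tsv --genome genome.tsv \
      --window 50000 --reps 2000 --seed 1 --out clustersim.tsv
k  sim_mean  sim_sd   observed  z     significant
1  76.8355   1.5171   76        -0.6  False
2  0.5785    0.7577   1          0.6  False
3  0.0025    0.0499   0         -0.1  False
```

No occupancy class deviates from the uniform null (|z| < 2) — correct,
since this generator run plants no clusters; planted-cluster recovery is
exercised by the test suite.

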