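"""Synthetic two-species probe-level data with known masking/DE ground truth.

The generator emulates the structure of a cross-species hybridization (CSH)
experiment: a reference species (the array's design species, one genotype)
and a target species (two genotypes) are profiled in two stem tissues (ES,
PES) with replication.  Probe-level log2 intensity is additive,

    log2 I = baseline_g + affinity_p + tissue_g * [PES] + genotype_g * [geno B]
             - d_isv * [p in ISV, target]  - d_sfp * [p in SFP, affected geno]
             + eps,   eps ~ N(0, sigma^2)

so replicate noise is lognormal on the linear scale.  Each probe also has
a small sequence-dependent response wobble per tissue (constant across
replicates and genotypes), so a summary built from very few probes is
systematically less reliable than one built from many — the reason masking
too aggressively costs accuracy.  The observed linear
intensity adds a nonspecific hybridization background on top of the
specific signal, ``X = 2**log2I + B`` with ``B ~ N(bg_mean, bg_sd)``
(clipped at 0) — the same convolution structure the normexp background
correction assumes.  This additive floor is what makes attenuated probes
lose fold-change information: a probe whose specific signal sits near or
below the background scale reports ratios compressed toward 1, which is
the cross-species bias the masking protocol exists to remove.

Inter-species variable (ISV) probes are attenuated in the target species
only, and divergence is a property of the gene: each gene draws a
divergence propensity, so a diverged minority of genes has most of its
probes ISV.  An ISV probe additionally cross-hybridizes: it picks up an
(equally attenuated) signal from one random unrelated gene, so its
tissue/genotype ratio is a mixture of two genes' patterns.  Attenuation
alone only shrinks ratios toward 1 — which the 2-fold selection filters
out — whereas cross-hybridization produces confidently wrong ratios, the
accuracy loss reported for cross-species hybridization.  SFP probes are attenuated in one target genotype only, again
in runs covering the majority of a probe set's probes, which is what makes
them capable of biasing the robust (median polish) summary.  The reference
species draws its own probe affinities and shares per-gene tissue effects
with the target at a configurable correlation.  Setting ``noise_sd`` to 0
switches off both the lognormal noise and the background variability, so
the generator is then fully deterministic given the planted effects.

Every planted quantity is returned as ground truth so each pipeline stage
can be scored without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Genome
from .io import LocusTable, ProbeIntensityMatrix, ProbeSetMap, SampleSheet

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "default_genome",
    "generate",
    "uniform_loci",
    "plant_cluster",
]


def default_genome(n_chromosomes: int = 8, total_bp: int = 266_102_767) -> Genome:
    """A compact legume-scale genome: 8 equal chromosomes, ~266 Mb total."""
    per = total_bp // n_chromosomes
    lengths = [per] * n_chromosomes
    lengths[-1] += total_bp - per * n_chromosomes
    return Genome(
        tuple(f"chr{i + 1}" for i in range(n_chromosomes)), tuple(lengths)
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults mirror the 2 genotypes x 2 tissues x 3 replicates CSH design
    with 11 PM probes per probe set.  Effects are log2 units.
    """

    n_probesets: int = 2000
    probes_per_set: int = 11
    genotypes: tuple[str, str] = ("A", "B")
    replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    probe_affinity_sd: float = 0.8
    tissue_effect_fraction: float = 0.15
    tissue_effect_sd: float = 1.5
    tissue_effect_min: float = 1.0  # affected genes have |log2 PES-ES| >= this
    cross_species_ratio_corr: float = 0.9
    genotype_de_fraction: float = 0.05
    genotype_effect_range: tuple[float, float] = (1.0, 3.0)
    isv_probe_fraction: float = 0.25
    isv_concentration: float = 2.0  # Beta concentration of per-gene divergence
    isv_attenuation: float = 3.0
    isv_crosshyb: bool = True  # ISV probes also bind one unrelated transcript
    sfp_probe_count: int = 200
    sfp_probes_per_set: int = 9
    sfp_attenuation: float = 2.5
    noise_sd: float = 0.3
    probe_condition_sd: float = 0.3  # probe x tissue response wobble (log2)
    background_mean: float = 100.0
    background_sd: float = 20.0
    seed: int = 0
    genome: Genome = field(default_factory=default_genome)

    def __post_init__(self) -> None:
        for name in ("tissue_effect_fraction", "genotype_de_fraction",
                     "isv_probe_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_probesets < 1 or self.probes_per_set < 1:
            raise ValueError("need at least one probe set and one probe per set")
        if not (1 <= self.sfp_probes_per_set <= self.probes_per_set):
            raise ValueError("sfp_probes_per_set must be in [1, probes_per_set]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for scoring every pipeline stage."""

    tissue_effect: pd.Series          # target species, per gene (0 = unaffected)
    ref_tissue_effect: pd.Series      # reference species, per gene
    genotype_effect: pd.Series        # target, per gene (geno B minus geno A)
    isv_probes: frozenset[str]
    sfp_probes: frozenset[str]
    sfp_affected_genotype: dict[str, str]   # probeset -> attenuated genotype
    sfp_genes: frozenset[str]
    de_genes: frozenset[str]          # genes with a nonzero genotype effect
    log2_signal_target: pd.DataFrame  # noise-free, attenuation-free log2 truth


@dataclass(frozen=True)
class SimData:
    target: ProbeIntensityMatrix
    reference: ProbeIntensityMatrix
    pmap: ProbeSetMap
    samples: SampleSheet
    sfp_list: list[str]
    loci: LocusTable
    truth: SimTruth


def _background(rng: np.random.Generator, config: SimConfig, n: int):
    """Per-probe nonspecific background; deterministic when noise_sd == 0."""
    if config.background_mean <= 0:
        return 0.0
    if config.noise_sd == 0 or config.background_sd == 0:
        return config.background_mean
    return np.maximum(
        rng.normal(config.background_mean, config.background_sd, n), 0.0
    )


def _truncated_effects(rng: np.random.Generator, n: int, sd: float,
                       minimum: float) -> np.ndarray:
    """Signed effects with |e| >= minimum, magnitude ~ |N(0, sd)| truncated."""
    mag = stats.truncnorm.rvs(minimum / sd, np.inf, loc=0.0, scale=sd,
                              size=n, random_state=rng)
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * mag


def generate(config: SimConfig) -> SimData:
    """Draw one synthetic dataset; fixed seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    n_sets = config.n_probesets
    ppx = config.probes_per_set
    gene_ids = np.array([f"ps{i:05d}" for i in range(n_sets)])
    probe_ids = np.array(
        [f"{g}_p{j + 1:02d}" for g in gene_ids for j in range(ppx)]
    )
    n_probes = n_sets * ppx
    gene_of_probe = np.repeat(np.arange(n_sets), ppx)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_sets)
    affinity_t = rng.normal(0.0, config.probe_affinity_sd, n_probes)
    affinity_r = rng.normal(0.0, config.probe_affinity_sd, n_probes)

    # per-gene tissue effects, shared between species at correlation rho
    tissue_e = np.zeros(n_sets)
    ref_tissue_e = np.zeros(n_sets)
    n_aff = int(round(config.tissue_effect_fraction * n_sets))
    affected = rng.choice(n_sets, size=n_aff, replace=False)
    e_t = _truncated_effects(rng, n_aff, config.tissue_effect_sd,
                             config.tissue_effect_min)
    rho = config.cross_species_ratio_corr
    e_r = rho * e_t + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(
        0.0, config.tissue_effect_sd, n_aff
    )
    tissue_e[affected] = e_t
    ref_tissue_e[affected] = e_r

    # genotype differential expression (target species only)
    geno_e = np.zeros(n_sets)
    n_de = int(round(config.genotype_de_fraction * n_sets))
    de_idx = rng.choice(n_sets, size=n_de, replace=False)
    lo, hi = config.genotype_effect_range
    geno_e[de_idx] = rng.choice([-1.0, 1.0], n_de) * rng.uniform(lo, hi, n_de)

    # SFP probes: runs within non-DE probe sets, each attenuated in one
    # genotype.  Hosts are drawn from genes expressed above the baseline
    # mean: real SFP lists are themselves called from hybridization signal,
    # so polymorphisms on weakly expressed genes go undetected.
    sfp_mask = np.zeros(n_probes, dtype=bool)
    sfp_affected: dict[str, str] = {}
    if config.sfp_probe_count > 0:
        n_sfp_sets = -(-config.sfp_probe_count // config.sfp_probes_per_set)
        expressed = np.flatnonzero(baseline >= config.baseline_log2_mean)
        candidates = np.setdiff1d(expressed, de_idx)
        if n_sfp_sets > candidates.size:
            raise ValueError("not enough expressed non-DE probe sets to host the SFPs")
        sfp_sets = rng.choice(candidates, size=n_sfp_sets, replace=False)
        remaining = config.sfp_probe_count
        for gi in sfp_sets:
            take = min(config.sfp_probes_per_set, remaining)
            within = rng.choice(ppx, size=take, replace=False)
            sfp_mask[gi * ppx + within] = True
            sfp_affected[gene_ids[gi]] = rng.choice(list(config.genotypes))
            remaining -= take
    sfp_genotype_code = np.zeros(n_probes, dtype=np.int8)  # 0 none, 1 genoA, 2 genoB
    for gi_name, geno in sfp_affected.items():
        gi = int(gi_name[2:])
        code = 1 + list(config.genotypes).index(geno)
        block = slice(gi * ppx, (gi + 1) * ppx)
        sfp_genotype_code[block] = np.where(sfp_mask[block], code, 0)

    # ISV probes (target species only).  Sequence divergence is a property
    # of the gene, so ISV membership is clustered: each gene draws a
    # divergence propensity from a low-concentration Beta (mean =
    # isv_probe_fraction), and its probes are ISV iid at that propensity.
    # Most genes end up with 0-1 ISV probes while a diverged minority has
    # most of its probes affected.
    if config.isv_probe_fraction > 0:
        a = config.isv_concentration * config.isv_probe_fraction
        b = config.isv_concentration * (1 - config.isv_probe_fraction)
        divergence = rng.beta(a, b, size=n_sets)
        isv_mask = rng.random(n_probes) < divergence[gene_of_probe]
    else:
        isv_mask = np.zeros(n_probes, dtype=bool)

    # sample sheets
    rows = []
    for geno in config.genotypes:
        for tissue in ("ES", "PES"):
            for rep in range(1, config.replicates + 1):
                rows.append((f"t_{geno}_{tissue}_{rep}", "target", geno, tissue, rep))
    for tissue in ("ES", "PES"):
        for rep in range(1, config.replicates + 1):
            rows.append((f"r_{tissue}_{rep}", "reference", "ref", tissue, rep))
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "species", "genotype", "tissue",
                                    "replicate"])
    )

    gene_base = baseline[gene_of_probe]
    tissue_probe = tissue_e[gene_of_probe]
    geno_probe = geno_e[gene_of_probe]
    ref_tissue_probe = ref_tissue_e[gene_of_probe]

    # cross-hybridization for ISV probes: a diverged gene's probes all bind
    # the same unrelated transcript (a paralog), at the same attenuation,
    # so the contamination is coherent across the probe set
    if config.isv_crosshyb:
        donor_gene = rng.integers(0, n_sets, size=n_sets)
        donor = donor_gene[gene_of_probe]
        xhyb_affinity = rng.normal(0.0, config.probe_affinity_sd, n_probes)

    # probe x tissue response wobble, shared by replicates and genotypes;
    # independent between species; off in the fully deterministic regime
    if config.noise_sd > 0 and config.probe_condition_sd > 0:
        wobble_t = rng.normal(0.0, config.probe_condition_sd, (n_probes, 2))
        wobble_r = rng.normal(0.0, config.probe_condition_sd, (n_probes, 2))
    else:
        wobble_t = wobble_r = np.zeros((n_probes, 2))

    target_cols, signal_cols = {}, {}
    for geno in config.genotypes:
        code = 1 + list(config.genotypes).index(geno)
        for tissue in ("ES", "PES"):
            is_pes = tissue == "PES"
            signal = (
                gene_base
                + affinity_t
                + (tissue_probe if is_pes else 0.0)
                + (geno_probe if geno == config.genotypes[1] else 0.0)
            )
            biased = (
                signal
                + wobble_t[:, int(is_pes)]
                - config.isv_attenuation * isv_mask
                - config.sfp_attenuation * (sfp_genotype_code == code)
            )
            for rep in range(1, config.replicates + 1):
                eps = rng.normal(0.0, config.noise_sd, n_probes) if config.noise_sd else 0.0
                linear = 2.0 ** (biased + eps)
                if config.isv_crosshyb and isv_mask.any():
                    xhyb = (
                        baseline[donor]
                        + xhyb_affinity
                        + tissue_e[donor] * is_pes
                        + geno_e[donor] * (geno == config.genotypes[1])
                        - config.isv_attenuation
                    )
                    eps2 = (
                        rng.normal(0.0, config.noise_sd, n_probes)
                        if config.noise_sd else 0.0
                    )
                    linear = linear + isv_mask * 2.0 ** (xhyb + eps2)
                target_cols[f"t_{geno}_{tissue}_{rep}"] = linear + _background(rng, config, n_probes)
                signal_cols[f"t_{geno}_{tissue}_{rep}"] = signal
    ref_cols = {}
    for tissue in ("ES", "PES"):
        is_pes = tissue == "PES"
        signal = (gene_base + affinity_r + (ref_tissue_probe if is_pes else 0.0)
                  + wobble_r[:, int(is_pes)])
        for rep in range(1, config.replicates + 1):
            eps = rng.normal(0.0, config.noise_sd, n_probes) if config.noise_sd else 0.0
            ref_cols[f"r_{tissue}_{rep}"] = 2.0 ** (signal + eps) + _background(rng, config, n_probes)

    idx = pd.Index(probe_ids, name="probe_id")
    target = ProbeIntensityMatrix(
        pd.DataFrame(target_cols, index=idx), sheet.subset("target"), "linear"
    )
    reference = ProbeIntensityMatrix(
        pd.DataFrame(ref_cols, index=idx), sheet.subset("reference"), "linear"
    )
    pmap = ProbeSetMap(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "probeset_id": gene_ids[gene_of_probe],
                "probe_index": np.tile(np.arange(1, ppx + 1), n_sets),
            }
        )
    )
    loci = uniform_loci(gene_ids, config.genome, rng)
    gene_index = pd.Index(gene_ids, name="probeset_id")
    truth = SimTruth(
        tissue_effect=pd.Series(tissue_e, index=gene_index),
        ref_tissue_effect=pd.Series(ref_tissue_e, index=gene_index),
        genotype_effect=pd.Series(geno_e, index=gene_index),
        isv_probes=frozenset(probe_ids[isv_mask]),
        sfp_probes=frozenset(probe_ids[sfp_mask]),
        sfp_affected_genotype=sfp_affected,
        sfp_genes=frozenset(sfp_affected),
        de_genes=frozenset(gene_ids[de_idx]),
        log2_signal_target=pd.DataFrame(signal_cols, index=idx),
    )
    return SimData(
        target=target,
        reference=reference,
        pmap=pmap,
        samples=sheet,
        sfp_list=sorted(probe_ids[sfp_mask]),
        loci=loci,
        truth=truth,
    )


def uniform_loci(probeset_ids, genome: Genome, rng_or_seed) -> LocusTable:
    """Place each probe set at an iid uniform position on the genome."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    probeset_ids = np.asarray(probeset_ids)
    cum = np.concatenate([[0], np.cumsum(genome.lengths)])
    gpos = rng.integers(0, genome.total_bp, size=probeset_ids.size)
    ci = np.searchsorted(cum, gpos, side="right") - 1
    return LocusTable(
        pd.DataFrame(
            {
                "probeset_id": probeset_ids,
                "chromosome": np.array(genome.chromosomes)[ci],
                "position_bp": gpos - cum[ci],
            }
        )
    )


def plant_cluster(loci: LocusTable, gene_ids, chromosome: str, start_bp: int,
                  span_bp: int, rng_or_seed=0) -> LocusTable:
    """Reposition the listed genes uniformly within [start, start + span)."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    gene_ids = list(gene_ids)
    t = loci.table.copy()
    present = t["probeset_id"].isin(gene_ids)
    if present.sum() != len(set(gene_ids)):
        missing = set(gene_ids) - set(t["probeset_id"])
        raise ValueError(f"genes absent from locus table: {sorted(missing)[:5]}")
    if not gene_ids:
        return loci
    t.loc[present, "chromosome"] = chromosome
    t.loc[present, "position_bp"] = rng.integers(
        start_bp, start_bp + span_bp, size=int(present.sum())
    )
    return LocusTable(t)
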