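"""Genome-window profiling and Monte Carlo clustering test of mapped genes.

Differentially expressed genes mapped to single loci are profiled in
sliding windows (default 50 kb shifted every 10 kb) and tested for
chromosomal clustering by a bin-occupancy simulation: the genome is cut
into non-overlapping windows, the observed number of bins holding exactly
k genes is compared with the mean and SD of the same statistic over many
random placements of the same number of genes, and |z| >= 2 flags
clustering at that occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LocusTable

__all__ = [
    "Genome",
    "GenomeBins",
    "ClusterSimResult",
    "sliding_window_frequency",
    "partition_bins",
    "observed_occupancy",
    "clustering_simulation",
    "z_scores",
    "results_to_frame",
]


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.lengths):
            raise ValueError("chromosomes and lengths differ in length")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.chromosomes.index(chrom)]

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "Genome":
        return cls(tuple(df["chromosome"]), tuple(int(x) for x in df["length_bp"]))


@dataclass(frozen=True)
class GenomeBins:
    """Non-overlapping windows [i*W, (i+1)*W) per chromosome, last truncated."""

    genome: Genome
    window_bp: int
    n_bins_per_chrom: tuple[int, ...]
    offsets: tuple[int, ...]  # global bin index of each chromosome's first bin

    @property
    def n_bins(self) -> int:
        return int(sum(self.n_bins_per_chrom))

    def assign(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Global bin index for each (chromosome, 0-based position) pair."""
        chrom_index = {c: i for i, c in enumerate(self.genome.chromosomes)}
        idx = np.array([chrom_index[c] for c in chroms])
        positions = np.asarray(positions, dtype=np.int64)
        lengths = np.asarray(self.genome.lengths)[idx]
        if np.any(positions >= lengths) or np.any(positions < 0):
            raise ValueError("locus position beyond chromosome length")
        return np.asarray(self.offsets)[idx] + positions // self.window_bp


def partition_bins(genome: Genome, window_bp: int) -> GenomeBins:
    """Cut each chromosome into ceil(length / W) fixed windows."""
    if window_bp <= 0:
        raise ValueError("window must be positive")
    counts = tuple(int(-(-l // window_bp)) for l in genome.lengths)
    offsets = tuple(int(x) for x in np.concatenate([[0], np.cumsum(counts)[:-1]]))
    return GenomeBins(genome, int(window_bp), counts, offsets)


def sliding_window_frequency(loci: LocusTable, genome: Genome,
                             window_bp: int = 50_000,
                             step_bp: int = 10_000) -> pd.DataFrame:
    """Count loci per sliding window [start, start+W), start = 0, step, ...

    Returns a tidy frame (chromosome, start_bp, count) covering every start
    below the chromosome length.  A window smaller than the step leaves
    gaps; that is allowed with a warning.
    """
    if window_bp < step_bp:
        import warnings

        warnings.warn("window smaller than step leaves uncovered gaps")
    frames = []
    t = loci.table
    for chrom, length in zip(genome.chromosomes, genome.lengths):
        pos = np.sort(t.loc[t["chromosome"] == chrom, "position_bp"].to_numpy())
        if np.any(pos >= length):
            raise ValueError(f"locus beyond end of {chrom}")
        starts = np.arange(0, length, step_bp, dtype=np.int64)
        counts = np.searchsorted(pos, starts + window_bp, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        frames.append(
            pd.DataFrame({"chromosome": chrom, "start_bp": starts, "count": counts})
        )
    return pd.concat(frames, ignore_index=True)


def observed_occupancy(loci: LocusTable, bins: GenomeBins) -> dict[int, int]:
    """Histogram {k: number of bins holding exactly k loci}, k >= 1."""
    t = loci.table
    if t.empty:
        return {}
    ids = bins.assign(t["chromosome"].to_numpy(), t["position_bp"].to_numpy())
    _, per_bin = np.unique(ids, return_counts=True)
    ks, nk = np.unique(per_bin, return_counts=True)
    return {int(k): int(n) for k, n in zip(ks, nk)}


def clustering_simulation(n_genes: int, genome: Genome, window_bp: int,
                          reps: int = 2000, null: str = "uniform_genome",
                          locus_universe: LocusTable | None = None,
                          seed: int | None = None) -> dict[int, tuple[float, float]]:
    """Null distribution of the bin-occupancy histogram.

    Per repetition, ``n_genes`` loci are placed (``uniform_genome``: iid
    uniform over the concatenated chromosomes; ``permute_loci``: sampled
    without replacement from ``locus_universe``) and the number of bins with
    exactly k loci recorded.  Returns {k: (mean, sd)} across repetitions
    (sd with n-1 denominator), for every k seen in at least one repetition.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    rng = np.random.default_rng(seed)
    bins = partition_bins(genome, window_bp)
    B = bins.n_bins

    if null == "uniform_genome":
        cum = np.concatenate([[0], np.cumsum(genome.lengths)])
        offsets_bp = cum[:-1]
        chrom_of = lambda gpos: np.searchsorted(cum, gpos, side="right") - 1
        gpos = rng.integers(0, genome.total_bp, size=(reps, n_genes))
        ci = chrom_of(gpos)
        within = gpos - offsets_bp[ci]
        gid = np.asarray(bins.offsets)[ci] + within // window_bp
    elif null == "permute_loci":
        if locus_universe is None or len(locus_universe) < n_genes:
            raise ValueError("permute_loci needs a universe with >= n_genes loci")
        t = locus_universe.table
        universe_ids = bins.assign(t["chromosome"].to_numpy(), t["position_bp"].to_numpy())
        gid = np.stack(
            [rng.choice(universe_ids, size=n_genes, replace=False) for _ in range(reps)]
        )
    else:
        raise ValueError(f"unknown null {null!r}")

    # occupancy per repetition without materializing all B bins: offset each
    # repetition into its own id space, then histogram the per-bin counts
    flat = (np.arange(reps)[:, None] * B + gid).ravel()
    uniq, per_bin = np.unique(flat, return_counts=True)
    rep_of = uniq // B
    kmax = int(per_bin.max())
    table = np.zeros((reps, kmax + 1), dtype=np.int64)
    np.add.at(table, (rep_of, per_bin), 1)
    out: dict[int, tuple[float, float]] = {}
    for k in range(1, kmax + 1):
        col = table[:, k]
        if col.any():
            out[k] = (float(col.mean()), float(col.std(ddof=1)))
    return out


@dataclass(frozen=True)
class ClusterSimResult:
    """One occupancy class k of the clustering test."""

    k: int
    sim_mean: float
    sim_sd: float
    observed: int
    z: float  # NaN when undefined; reported rounded to 1 decimal
    significant: bool
    flagged: bool  # True when z is undefined (sd 0 or k never simulated)


def z_scores(observed: dict[int, int],
             sim: dict[int, tuple[float, float]]) -> list[ClusterSimResult]:
    """(observed - sim mean) / sim SD per occupancy k; |z| >= 2 significant.

    k values observed but never produced by the simulation, or with zero
    simulation SD and observed != mean, are flagged with an undefined z
    rather than an infinite one.
    """
    results = []
    for k in sorted(set(observed) | set(sim)):
        obs = int(observed.get(k, 0))
        if k not in sim:
            results.append(ClusterSimResult(k, float("nan"), float("nan"), obs,
                                            float("nan"), False, True))
            continue
        mean, sd = sim[k]
        if sd == 0:
            if obs == mean:
                results.append(ClusterSimResult(k, mean, sd, obs, 0.0, False, False))
            else:
                results.append(ClusterSimResult(k, mean, sd, obs, float("nan"),
                                                False, True))
            continue
        z = (obs - mean) / sd
        results.append(
            ClusterSimResult(k, mean, sd, obs, round(z, 1), bool(abs(z) >= 2), False)
        )
    return results


def results_to_frame(results: list[ClusterSimResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": [r.k for r in results],
            "sim_mean": [r.sim_mean for r in results],
            "sim_sd": [r.sim_sd for r in results],
            "observed": [r.observed for r in results],
            "z": [r.z for r in results],
            "significant": [r.significant for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
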