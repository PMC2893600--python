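"""Genome windows, bin occupancy and the Monte Carlo clustering test."""

import math

import numpy as np
import pandas as pd
import pytest

from xmask.cluster import (
    Genome,
    clustering_simulation,
    observed_occupancy,
    partition_bins,
    sliding_window_frequency,
    z_scores,
)
from xmask.io import LocusTable


def loci_from(pairs):
    return LocusTable(pd.DataFrame(
        [(f"g{i}", c, p) for i, (c, p) in enumerate(pairs)],
        columns=["probeset_id", "chromosome", "position_bp"]))


GENOME = Genome(("chr1", "chr2"), (200_000, 101_000))


def test_sliding_window_no_loci_all_zero():
    prof = sliding_window_frequency(loci_from([]), GENOME)
    assert (prof["count"] == 0).all()
    assert set(prof["chromosome"]) == {"chr1", "chr2"}


def test_sliding_window_single_locus_hits_five_windows():
    prof = sliding_window_frequency(loci_from([("chr1", 55_000)]), GENOME,
                                    50_000, 10_000)
    hit = prof[(prof["chromosome"] == "chr1") & (prof["count"] > 0)]
    assert list(hit["start_bp"]) == [10_000, 20_000, 30_000, 40_000, 50_000]
    assert (hit["count"] == 1).all()


def test_sliding_window_matches_bruteforce_recount():
    rng = np.random.default_rng(12)
    pairs = [("chr1", int(p)) for p in rng.integers(0, 200_000, 60)]
    prof = sliding_window_frequency(loci_from(pairs), GENOME, 50_000, 10_000)
    sub = prof[prof["chromosome"] == "chr1"]
    pos = [p for _, p in pairs]
    for _, row in sub.iloc[::3].iterrows():
        want = sum(row.start_bp <= p < row.start_bp + 50_000 for p in pos)
        assert row["count"] == want
    # interior loci are counted in exactly window/step windows
    interior = [p for p in pos if 50_000 <= p < 150_000]
    total_from_interior = sum(
        sum(s <= p < s + 50_000 for p in interior) for s in sub["start_bp"])
    assert total_from_interior == 5 * len(interior)


def test_partition_bins_ceil_rule():
    g = Genome(("c1",), (100_000,))
    assert partition_bins(g, 50_000).n_bins == 2
    g2 = Genome(("c1",), (101_000,))
    assert partition_bins(g2, 50_000).n_bins == 3
    rng = np.random.default_rng(3)
    lengths = tuple(int(x) for x in rng.integers(10_000, 5_000_000, 12))
    g3 = Genome(tuple(f"c{i}" for i in range(12)), lengths)
    assert partition_bins(g3, 70_000).n_bins == sum(
        math.ceil(l / 70_000) for l in lengths)


def test_observed_occupancy_examples():
    bins = partition_bins(GENOME, 50_000)
    spread = loci_from([("chr1", 10), ("chr1", 60_000), ("chr2", 10)])
    assert observed_occupancy(spread, bins) == {1: 3}
    packed = loci_from([("chr1", 10), ("chr1", 20), ("chr1", 30)])
    assert observed_occupancy(packed, bins) == {3: 1}
    with pytest.raises(ValueError):
        observed_occupancy(loci_from([("chr2", 500_000)]), bins)


def test_observed_occupancy_matches_bruteforce():
    rng = np.random.default_rng(7)
    pairs = [("chr1", int(p)) for p in rng.integers(0, 200_000, 100)]
    bins = partition_bins(GENOME, 50_000)
    got = observed_occupancy(loci_from(pairs), bins)
    counts = {}
    for _, p in pairs:
        counts[p // 50_000] = counts.get(p // 50_000, 0) + 1
    want = {}
    for k in counts.values():
        want[k] = want.get(k, 0) + 1
    assert got == want


def test_simulation_single_gene_degenerate():
    sim = clustering_simulation(1, GENOME, 50_000, reps=10, seed=0)
    assert sim == {1: (1.0, 0.0)}


def test_simulation_fixed_seed_bit_identical():
    a = clustering_simulation(40, GENOME, 50_000, reps=200, seed=42)
    b = clustering_simulation(40, GENOME, 50_000, reps=200, seed=42)
    assert a == b


def test_simulation_mean_matches_binomial_occupancy_closed_form():
    """With B equal bins and N genes placed uniformly, the expected number
    of bins holding exactly k genes is B*C(N,k)(1/B)^k(1-1/B)^(N-k); the
    simulated means at 2000 repetitions agree within 3 Monte Carlo SEs."""
    g = Genome(("c1", "c2"), (500_000, 500_000))  # 20 equal 50 kb bins
    B, N, reps = 20, 30, 2000
    sim = clustering_simulation(N, g, 50_000, reps=reps, seed=7)
    for k, (mean, sd) in sim.items():
        expect = B * math.comb(N, k) * (1 / B) ** k * (1 - 1 / B) ** (N - k)
        assert abs(mean - expect) <= 3 * sd / math.sqrt(reps) + 1e-12, k


def test_simulation_occupancy_conserves_genes():
    """Sum of k * count(k) equals the number of genes placed, every rep."""
    rng = np.random.default_rng(5)
    n = 37
    sim = clustering_simulation(n, GENOME, 50_000, reps=300, seed=11)
    total = sum(k * mean for k, (mean, _) in sim.items())
    assert np.isclose(total, n, atol=1e-9)


def test_simulation_permute_loci_null():
    rng = np.random.default_rng(9)
    pairs = [("chr1", int(p)) for p in rng.integers(0, 200_000, 80)]
    universe = loci_from(pairs)
    sim = clustering_simulation(30, GENOME, 50_000, reps=100,
                                null="permute_loci", locus_universe=universe,
                                seed=1)
    assert sum(k * m for k, (m, _) in sim.items()) == pytest.approx(30)
    with pytest.raises(ValueError):
        clustering_simulation(100, GENOME, 50_000, null="permute_loci",
                              locus_universe=universe, seed=1)


def test_simulation_validates_args():
    with pytest.raises(ValueError):
        clustering_simulation(0, GENOME, 50_000, seed=1)
    with pytest.raises(ValueError):
        clustering_simulation(5, GENOME, 50_000, reps=1, seed=1)
    with pytest.raises(ValueError):
        clustering_simulation(5, GENOME, 50_000, null="bogus", seed=1)


def test_z_scores_observed_equals_mean_and_flags():
    res = z_scores({1: 10, 3: 1}, {1: (10.0, 2.0), 2: (1.0, 0.5)})
    by_k = {r.k: r for r in res}
    assert by_k[1].z == 0.0 and not by_k[1].significant
    assert by_k[2].observed == 0 and by_k[2].z == -2.0 and by_k[2].significant
    assert by_k[3].flagged and math.isnan(by_k[3].z)
    # zero SD with a different observation is flagged, not infinite
    res2 = z_scores({1: 5}, {1: (4.0, 0.0)})
    assert res2[0].flagged and math.isnan(res2[0].z)
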