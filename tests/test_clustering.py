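"""Tag clustering, interquantile widths and shape/CpG classes.

The clustering and quantile operations are checked against independent
brute-force oracles: an O(n^2) single-linkage partition for the gap
rule, and a cumulative-sum walk for the quantile positions.
"""

import numpy as np
import pandas as pd
import pytest

import promarch as pa
from promarch.clustering import interquantile_width, dominant_ctss

from conftest import make_ctss_table


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def single_linkage_oracle(positions, max_gap=20):
    """O(n^2) connected components: edge when |pi - pj| <= max_gap."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(positions[i])
    return {frozenset(g) for g in groups.values()}


def quantile_oracle(positions, tpms, strand, q_lo=0.1, q_hi=0.9):
    """Walk positions 5'->3', accumulate tpm, stop at the stated fractions."""
    order = np.argsort(positions)
    if strand == "-":
        order = order[::-1]
    pos = np.asarray(positions)[order]
    t = np.asarray(tpms, dtype=float)[order]
    total = t.sum()
    cum = 0.0
    lo = hi = None
    for p, v in zip(pos, t):
        cum += v
        if lo is None and cum >= q_lo * total - 1e-9 * total:
            lo = p
        if hi is None and cum >= q_hi * total - 1e-9 * total:
            hi = p
            break
    return min(lo, hi), max(lo, hi)


def cluster_positions(table, **kw):
    return {frozenset(c.positions.tolist())
            for c in pa.cluster_ctss(table, **kw)}


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_gap_boundary_20_merges_21_splits():
    t = make_ctss_table([100, 120], [100, 100])
    assert len(pa.cluster_ctss(t)) == 1
    t = make_ctss_table([100, 121], [100, 100])
    assert len(pa.cluster_ctss(t)) == 2


def test_low_tpm_ctss_discarded_before_clustering():
    # 1 count of 1e6 total = 1 tpm (kept); bridge position below 1 tpm removed,
    # so the remaining CTSSes are 40 bp apart and split
    df = make_ctss_table([100, 120, 140], [100, 0, 100], normalize=False)
    df.loc[1, "count"] = 1
    t = pa.normalize_tpm(df, library_size=10_000_000)  # bridge: 0.1 tpm
    clusters = pa.cluster_ctss(t, min_singleton_tpm=0.0)
    assert len(clusters) == 2


def test_singleton_below_5tpm_dropped():
    df = make_ctss_table([100, 500], [100, 4], normalize=False)
    t = pa.normalize_tpm(df, library_size=1_000_000)  # tpm == count
    clusters = pa.cluster_ctss(t)
    assert [c.start for c in clusters] == [100]


def test_clusters_never_span_chrom_or_strand():
    df = pd.concat([
        make_ctss_table([100, 110], [50, 50], chrom="chr1", strand="+",
                        normalize=False),
        make_ctss_table([105, 115], [50, 50], chrom="chr1", strand="-",
                        normalize=False),
        make_ctss_table([100, 110], [50, 50], chrom="chr2", strand="+",
                        normalize=False),
    ], ignore_index=True)
    t = pa.normalize_tpm(df)
    clusters = pa.cluster_ctss(t)
    assert len(clusters) == 3
    assert all(len({(c.chrom, c.strand)}) == 1 for c in clusters)


def test_partition_matches_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(1, 60))
        positions = np.unique(rng.integers(1, 2000, n))
        counts = rng.integers(10, 100, len(positions))
        t = make_ctss_table(positions, counts)
        got = cluster_positions(t, min_singleton_tpm=0.0)
        assert got == single_linkage_oracle(positions.tolist())


def test_every_retained_ctss_in_exactly_one_cluster():
    rng = np.random.default_rng(1)
    positions = np.unique(rng.integers(1, 5000, 200))
    counts = rng.integers(1, 50, len(positions))
    t = make_ctss_table(positions, counts)
    clusters = pa.cluster_ctss(t, min_singleton_tpm=0.0)
    seen = [p for c in clusters for p in c.positions.tolist()]
    assert sorted(seen) == sorted(positions.tolist())


# ---------------------------------------------------------------------------
# dominant CTSS
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tpms,positions,strand,expect", [
    ((1, 5, 2), (10, 11, 12), "+", 11),
    ((5, 5), (10, 11), "+", 10),   # tie -> 5'-most on plus
    ((5, 5), (10, 11), "-", 11),   # tie -> 5'-most on minus
])
def test_dominant_ctss_and_tie_rules(tpms, positions, strand, expect):
    pos, tpm = dominant_ctss(np.array(positions), np.array(tpms), strand)
    assert pos == expect and tpm == max(tpms)


# ---------------------------------------------------------------------------
# interquantile width
# ---------------------------------------------------------------------------

def test_single_ctss_width_is_one():
    assert interquantile_width(np.array([500]), np.array([9.0]), "+") == \
        (500, 500, 1)


def test_ten_equal_consecutive_positions_width_nine():
    pos = np.arange(1000, 1010)
    tpm = np.full(10, 3.0)
    q_low, q_up, width = interquantile_width(pos, tpm, "+")
    assert (q_low, q_up, width) == (1000, 1008, 9)


def test_width_matches_cumulative_oracle_on_random_clusters():
    rng = np.random.default_rng(2)
    for _ in range(500):
        n = int(rng.integers(1, 40))
        pos = np.unique(rng.integers(1, 3000, n))
        tpm = rng.uniform(0.1, 50, len(pos))
        strand = "+" if rng.random() < 0.5 else "-"
        q_low, q_up, width = interquantile_width(pos, tpm, strand)
        lo, hi = quantile_oracle(pos, tpm, strand)
        assert (q_low, q_up) == (lo, hi)
        assert width == hi - lo + 1


def test_strand_mirror_gives_identical_width():
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = int(rng.integers(1, 30))
        pos = np.unique(rng.integers(1, 1000, n))
        tpm = rng.uniform(0.5, 20, len(pos))
        L = 2000
        mirror_pos = (L - pos)[::-1]
        mirror_tpm = tpm[::-1]
        w_fwd = interquantile_width(pos, tpm, "+")[2]
        w_rev = interquantile_width(mirror_pos, mirror_tpm, "-")[2]
        assert w_fwd == w_rev


# ---------------------------------------------------------------------------
# shape classes
# ---------------------------------------------------------------------------

def test_shape_recovery_on_planted_architectures(small_study):
    genome, truth, ctss = (small_study["genome"], small_study["truth"],
                           small_study["ctss"])
    tables = {s: pa.normalize_tpm(df) for s, df in ctss.items()}
    pooled = []
    for s, t in tables.items():
        t.attrs["stage"] = s
        pooled.extend(pa.cluster_ctss(t))
    pa.classify_shape(pooled)
    frame = pa.clusters_to_frame(pooled)
    sharp_med = frame[frame.shape_class == "sharp"].iq_width.median()
    broad_med = frame[frame.shape_class == "broad"].iq_width.median()
    assert sharp_med < broad_med


def test_identical_widths_all_intermediate():
    clusters = [
        pa.cluster_ctss(make_ctss_table([100 * i], [100]))[0]
        for i in range(1, 5)
    ]
    pa.classify_shape(clusters)
    assert all(c.shape_class == "intermediate" for c in clusters)


# ---------------------------------------------------------------------------
# CpG classes
# ---------------------------------------------------------------------------

def test_all_a_window_frequency_zero_lcg(toy_genome):
    assert pa.cpg_frequency(toy_genome, "chr1", 2500) == 0.0


def test_cg_repeat_window_maximal_frequency():
    g = pa.Genome({"chr1": "CG" * 1000})
    freq = pa.cpg_frequency(g, "chr1", 1001)  # window phase starts on C
    assert freq == pytest.approx(100 / 199)


def test_cpg_frequency_matches_sliding_oracle():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), 3000))
    g = pa.Genome({"chr1": seq})
    for center in (200, 1500, 2500):
        # window is the closed interval [center-100, center+99], 1-based
        sub = seq[center - 101 : center + 99]
        oracle = sum(1 for i in range(len(sub) - 1)
                     if sub[i : i + 2] == "CG") / 199
        assert pa.cpg_frequency(g, "chr1", center) == pytest.approx(oracle)


def test_cpg_classes_partition_pooled_set(small_study):
    genome, ctss = small_study["genome"], small_study["ctss"]
    t = pa.normalize_tpm(ctss["male"])
    clusters = pa.cluster_ctss(t)
    pa.classify_cpg(clusters, genome)
    classes = {c.cpg_class for c in clusters}
    assert classes <= {"LCG", "mid", "HCG"}
    assert all(c.cpg_frequency is not None for c in clusters)
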