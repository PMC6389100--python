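"""Gene/operon assignment, SL trans-splicing rules, acceptor exclusion."""

import itertools

import numpy as np
import pandas as pd
import pytest

import promarch as pa
from promarch.clustering import TagCluster


def cluster_at(pos, chrom="chr1", strand="+", cid="c1"):
    return TagCluster(id=cid, stage=None, chrom=chrom, strand=strand,
                      start=pos, end=pos, dominant_pos=pos, dominant_tpm=10.0,
                      total_tpm=10.0, q_low=pos, q_up=pos, iq_width=1)


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "operon_id", "operon_pos"])


GENES = gene_frame([
    ("gA", "chr1", 2000, 3000, "+", None, 0),
    ("gB", "chr1", 6000, 7000, "-", None, 0),
    ("op1", "chr1", 10000, 10800, "+", "opX", 1),
    ("op2", "chr1", 11000, 11800, "+", "opX", 2),
])


def test_ctss_400bp_upstream_assigned_as_upstream():
    out = pa.assign_to_genes([cluster_at(1600)], GENES)
    assert out.loc[0, "gene_id"] == "gA"
    assert out.loc[0, "relation"] == "in_upstream_500"


def test_ctss_501bp_upstream_unassigned():
    out = pa.assign_to_genes([cluster_at(1499)], GENES)
    assert out.empty


def test_minus_strand_upstream_window():
    # gB upstream is genomically downstream: [7001, 7500]
    out = pa.assign_to_genes([cluster_at(7400, strand="-")], GENES)
    assert out.loc[0, "gene_id"] == "gB"
    assert pa.assign_to_genes([cluster_at(7501, strand="-")], GENES).empty


def test_assignment_matches_exhaustive_interval_oracle():
    rng = np.random.default_rng(0)
    genes = gene_frame([
        (f"g{i}", "chr1", s, s + 800, "+" if i % 2 else "-", None, 0)
        for i, s in enumerate(sorted(rng.integers(1000, 50_000, 40)))
    ])
    clusters = [cluster_at(int(p), strand=("+" if rng.random() < 0.5 else "-"),
                           cid=f"c{j}")
                for j, p in enumerate(rng.integers(1, 52_000, 300))]
    got = pa.assign_to_genes(clusters, genes).set_index("cluster_id")
    for c in clusters:
        matches = []
        for _, g in genes.iterrows():
            if g["strand"] != c.strand:
                continue
            lo = g["start"] - 500 if g["strand"] == "+" else g["start"]
            hi = g["end"] if g["strand"] == "+" else g["end"] + 500
            if lo <= c.dominant_pos <= hi:
                matches.append(g)
        if not matches:
            assert c.id not in got.index
        else:
            assert c.id in got.index
            tss = lambda g: g["start"] if g["strand"] == "+" else g["end"]
            best = min(matches, key=lambda g: abs(c.dominant_pos - tss(g)))
            assert got.loc[c.id, "gene_id"] == best["gene_id"]


# ---------------------------------------------------------------------------
# SL classification: exhaustive truth table of the three conditions
# ---------------------------------------------------------------------------

def test_sl_truth_table_all_condition_combinations():
    """is_trans_spliced iff AG acceptor present AND count > 1 AND site in
    the gene window — checked for all 8 combinations."""
    for has_ag, count_ok, in_window in itertools.product([True, False],
                                                         repeat=3):
        seq = list("T" * 10_000)
        gene = gene_frame([("g1", "chr1", 3000, 4000, "+", None, 0)])
        pos = 3010 if in_window else 6000
        if has_ag:
            seq[pos - 3 : pos - 1] = list("AG")
        genome = pa.Genome({"chr1": "".join(seq)})
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [pos],
                              "strand": ["+"],
                              "count": [3 if count_ok else 1]})
        out = pa.classify_sl(gene, sites, genome)
        expect = has_ag and count_ok and in_window
        assert bool(out.loc[0, "is_trans_spliced"]) == expect, \
            (has_ag, count_ok, in_window)


def test_sl_minus_strand_acceptor_orientation():
    # site at 5000 on minus strand: upstream AG occupies genomic 5001-5002
    seq = list("T" * 10_000)
    seq[5000:5002] = list("CT")  # revcomp(AG)
    genome = pa.Genome({"chr1": "".join(seq)})
    gene = gene_frame([("g1", "chr1", 4000, 5400, "-", None, 0)])
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [5000],
                          "strand": ["-"], "count": [5]})
    out = pa.classify_sl(gene, sites, genome)
    assert bool(out.loc[0, "is_trans_spliced"])


def _fresh_study(seed=70):
    """Own study for tests that mutate genome/truth via SL simulation."""
    genome, genes = pa.generate_genome(n_chrom=2, chrom_len=120_000, seed=seed)
    truth = pa.plant_promoters(genome, genes, pa.default_archetypes(),
                               n_per_archetype=5, seed=seed + 1,
                               internal_archetypes=("male_sharp_tctaga",))
    return genome, genes, truth


def test_sl_classification_idempotent():
    genome, genes, truth = _fresh_study(70)
    sl = pa.simulate_sl_sites(genome, truth, genes, fraction_sl=0.3, seed=50)
    a = pa.classify_sl(genes, sl, genome)
    b = pa.classify_sl(genes, sl, genome)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# operon-internal promoters
# ---------------------------------------------------------------------------

def test_cluster_at_second_operon_gene_is_internal():
    out = pa.find_internal_promoters([cluster_at(10950, cid="c9")], GENES)
    assert list(out["gene_id"]) == ["op2"]
    assert list(out["operon_pos"]) == [2]


def test_cluster_at_first_operon_gene_not_internal():
    out = pa.find_internal_promoters([cluster_at(9800, cid="c9")], GENES)
    assert out.empty


def test_planted_internal_promoters_all_recovered(small_study):
    genome, genes, truth = (small_study["genome"], small_study["genes"],
                            small_study["truth"])
    ctss = small_study["ctss"]
    t = pa.normalize_tpm(ctss["male"])
    clusters = pa.cluster_ctss(t)
    internal = pa.find_internal_promoters(clusters, genes)
    internal_genes = set(internal["gene_id"])
    planted = {p.gene_id for p in truth.promoters.values()
               if p.operon_internal}
    assert planted <= internal_genes
    # never at an operon's first gene
    first = set(genes[genes["operon_pos"] == 1]["gene_id"])
    assert not (internal_genes & first)


# ---------------------------------------------------------------------------
# SL exclusion
# ---------------------------------------------------------------------------

def _exclusion_setup():
    # TCTAGA with 5' base at 1956, TSS at 2000 (offset 44, + strand)
    seq = list("T" * 5000)
    seq[1955:1961] = list("TCTAGA")
    genome = pa.Genome({"chr1": "".join(seq)})
    cluster = cluster_at(2000)
    return genome, cluster


def test_planted_exclusion_event_detected():
    genome, cluster = _exclusion_setup()
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1961],
                          "strand": ["+"], "count": [4]})
    out = pa.detect_sl_exclusion([cluster], sites, genome)
    assert len(out) == 1
    assert out.loc[0, "acceptor_pos"] == 1961
    assert out.loc[0, "motif_start"] == 1956


def test_tctaga_without_site_at_its_aga_no_event():
    genome, cluster = _exclusion_setup()
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1980],
                          "strand": ["+"], "count": [4]})
    assert pa.detect_sl_exclusion([cluster], sites, genome).empty


def test_acceptor_entirely_upstream_of_motif_no_event():
    genome, cluster = _exclusion_setup()
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1900],
                          "strand": ["+"], "count": [4]})
    assert pa.detect_sl_exclusion([cluster], sites, genome).empty


def test_synthetic_exclusion_events_recovered_exactly():
    genome, genes, truth = _fresh_study(80)
    sl = pa.simulate_sl_sites(genome, truth, genes, fraction_sl=0.2, seed=60,
                              n_exclusion=4)
    ctss = pa.simulate_cage(genome, truth, depth=100_000, seed=61)
    clusters = pa.cluster_ctss(pa.normalize_tpm(ctss["male"]))
    out = pa.detect_sl_exclusion(clusters, sl, genome)
    planted = {(p.chrom, p.sl_sites[0][1])
               for p in truth.promoters.values() if p.sl_exclusion}
    got = {(r["chrom"], r["acceptor_pos"]) for _, r in out.iterrows()}
    assert got == planted


# ---------------------------------------------------------------------------
# promoter-mark intersection
# ---------------------------------------------------------------------------

def test_region_touching_window_edge_counts_as_overlap():
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [1000],
                            "end": [1500]})
    # + strand start at 2000: window [1500, 2100] — 1 bp overlap at 1500
    assert pa.intersect_promoter_marks(regions, [("chr1", "+", 2000)])[0]


def test_region_wholly_600bp_upstream_no_overlap():
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [1000],
                            "end": [1399]})
    assert not pa.intersect_promoter_marks(regions, [("chr1", "+", 2000)])[0]


def test_mark_intersection_matches_interval_oracle():
    rng = np.random.default_rng(1)
    starts = rng.integers(1000, 50_000, 50)
    regions = pd.DataFrame({
        "chrom": "chr1", "start": starts,
        "end": starts + rng.integers(50, 500, 50)})
    sites = [("chr1", "+" if rng.random() < 0.5 else "-",
              int(p)) for p in rng.integers(1, 52_000, 200)]
    got = pa.intersect_promoter_marks(regions, sites)
    for ok, (chrom, strand, pos) in zip(got, sites):
        lo, hi = (pos - 500, pos + 100) if strand == "+" else (pos - 100,
                                                               pos + 500)
        expect = any(r["start"] <= hi and r["end"] >= lo
                     for _, r in regions.iterrows())
        assert bool(ok) == expect
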