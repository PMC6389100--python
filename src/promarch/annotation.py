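"""Gene/operon assignment, SL trans-splicing calls and acceptor exclusion.

Promoters are tied to gene models when their dominant CTSS falls in the
gene body or the 500 bp upstream region (strand-aware). A gene is
called spliced-leader (SL) trans-spliced when an SL site lies in the
same window, is supported by more than one tag, and has an AG acceptor
dinucleotide immediately upstream in the reference. Operon-internal
promoters are tag clusters assigned to an operon gene other than the
operon's first gene. An SL-exclusion event is a TCTAGA core-promoter
motif whose AGA overlaps a trans-splice acceptor (motif positions 4-5 =
the acceptor AG) with the dominant TSS downstream of the acceptor, so
transcripts from that TSS cannot be trans-spliced.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .synthetic import acceptor_ok

logger = logging.getLogger(__name__)

UPSTREAM = 500  # bp upstream of a gene's 5' end counted as promoter territory


def _gene_window(g, upstream: int = UPSTREAM) -> tuple[int, int]:
    """Closed genomic interval: gene body plus `upstream` bp 5' of it."""
    if g["strand"] == "+":
        return int(g["start"]) - upstream, int(g["end"])
    return int(g["start"]), int(g["end"]) + upstream


def assign_to_genes(clusters, genes: pd.DataFrame,
                    upstream: int = UPSTREAM) -> pd.DataFrame:
    """Assign each tag cluster to a gene by its dominant CTSS.

    A cluster is assigned when its dominant CTSS overlaps a same-strand
    gene body or the gene's ``upstream`` bp region. When several genes'
    windows overlap the CTSS, the gene whose annotated start (5' end)
    is nearest wins; remaining ties go to the 5'-most gene on the
    cluster's strand (frequency logged). Returns one row per assigned
    cluster: cluster_id, gene_id, relation, operon_id, operon_pos.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gi, g in genes.iterrows():
        lo, hi = _gene_window(g, upstream)
        trees.setdefault((g["chrom"], g["strand"]), IntervalTree()
                         ).addi(lo, hi + 1, gi)
    rows, ties = [], 0
    for c in clusters:
        tree = trees.get((c.chrom, c.strand))
        if tree is None:
            continue
        hits = [iv.data for iv in tree.at(c.dominant_pos)]
        if not hits:
            continue
        if len(hits) > 1:
            def tss(gi):
                g = genes.loc[gi]
                return int(g["start"]) if g["strand"] == "+" else int(g["end"])
            dists = {gi: abs(c.dominant_pos - tss(gi)) for gi in hits}
            dmin = min(dists.values())
            nearest = [gi for gi, d in dists.items() if d == dmin]
            if len(nearest) > 1:
                ties += 1
                nearest.sort(key=lambda gi: tss(gi),
                             reverse=(c.strand == "-"))
            hits = [nearest[0]]
        g = genes.loc[hits[0]]
        in_body = int(g["start"]) <= c.dominant_pos <= int(g["end"])
        rows.append({
            "cluster_id": c.id, "gene_id": g["gene_id"],
            "relation": "in_gene_body" if in_body else "in_upstream_500",
            "operon_id": g["operon_id"], "operon_pos": int(g["operon_pos"]),
        })
    if ties:
        logger.info("assign_to_genes: %d nearest-start ties broken 5'-most", ties)
    return pd.DataFrame(rows, columns=["cluster_id", "gene_id", "relation",
                                       "operon_id", "operon_pos"])


def classify_sl(genes: pd.DataFrame, sl_sites: pd.DataFrame, genome,
                upstream: int = UPSTREAM, min_count: int = 2) -> pd.DataFrame:
    """SL trans-splicing status per gene.

    A gene is trans-spliced when at least one SL site (i) lies within
    the gene body or its ``upstream`` bp region on the same strand,
    (ii) is supported by more than one tag (count >= ``min_count``) and
    (iii) has an AG immediately upstream (strand-aware) in the
    reference. The highest-count passing site is recorded as support.
    """
    rows = []
    for _, g in genes.iterrows():
        lo, hi = _gene_window(g, upstream)
        m = ((sl_sites["chrom"] == g["chrom"])
             & (sl_sites["strand"] == g["strand"])
             & (sl_sites["pos"] >= lo) & (sl_sites["pos"] <= hi))
        sub = sl_sites[m]
        best = None
        best_ok = False
        for _, s in sub.sort_values("count", ascending=False).iterrows():
            ok_ag = acceptor_ok(genome, s["chrom"], int(s["pos"]), s["strand"])
            ok = ok_ag and int(s["count"]) >= min_count
            if best is None or (ok and not best_ok):
                best, best_ok = s, ok
            if ok:
                break
        rows.append({
            "gene_id": g["gene_id"],
            "is_trans_spliced": bool(best_ok),
            "sl_chrom": best["chrom"] if best is not None else None,
            "sl_pos": int(best["pos"]) if best is not None else None,
            "sl_count": int(best["count"]) if best is not None else 0,
            "acceptor_ok": bool(best is not None and acceptor_ok(
                genome, best["chrom"], int(best["pos"]), best["strand"])),
        })
    return pd.DataFrame(rows)


def find_internal_promoters(clusters, genes: pd.DataFrame,
                            assignments: pd.DataFrame | None = None
                            ) -> pd.DataFrame:
    """Tag clusters acting as operon-internal promoters.

    A cluster is operon-internal when its dominant CTSS is assigned to
    an operon gene with operon_pos >= 2 (i.e. not the operon's first
    gene). Returns cluster_id, operon_id, gene_id, operon_pos.
    """
    if assignments is None:
        assignments = assign_to_genes(clusters, genes)
    internal = assignments[(assignments["operon_id"].notna())
                           & (assignments["operon_pos"] >= 2)]
    return (internal[["cluster_id", "operon_id", "gene_id", "operon_pos"]]
            .reset_index(drop=True))


def detect_sl_exclusion(clusters, sl_sites: pd.DataFrame, genome,
                        motif: str = "TCTAGA",
                        window: tuple[int, int] = (22, 101)) -> pd.DataFrame:
    """Find motif-driven exclusion of trans-splice acceptor sites.

    For each tag cluster, TCTAGA occurrences are sought in the upstream
    window (motif 5'-base offset within ``window`` of the dominant
    CTSS, strand-aware). An exclusion event is emitted when the motif's
    AG (positions 4-5) coincides genomically with an SL acceptor's AG --
    equivalently, the trans-splice site sits at motif base 6 -- and the
    dominant CTSS lies 3' of the acceptor, so transcripts initiated
    there cannot contain it.
    """
    site_keys = {(r["chrom"], int(r["pos"]), r["strand"])
                 for _, r in sl_sites.iterrows()}
    lo, hi = min(window), max(window)
    rows = []
    for c in clusters:
        sign = 1 if c.strand == "+" else -1
        for off in range(lo, hi + 1):
            m5 = c.dominant_pos - sign * off  # genomic pos of motif 5' base
            start = min(m5, m5 + sign * (len(motif) - 1))
            end = max(m5, m5 + sign * (len(motif) - 1))
            if start < 1 or end > genome.length(c.chrom):
                continue
            if genome.fetch(c.chrom, start, end, c.strand) != motif:
                continue
            acceptor = m5 + sign * 5  # trans-splice junction at motif base 6
            if (c.chrom, acceptor, c.strand) not in site_keys:
                continue
            downstream = (c.dominant_pos >= acceptor if c.strand == "+"
                          else c.dominant_pos <= acceptor)
            if not downstream:
                continue
            rows.append({
                "cluster_id": c.id, "chrom": c.chrom, "strand": c.strand,
                "motif_start": m5, "acceptor_pos": acceptor,
                "dominant_pos": c.dominant_pos, "offset": off,
            })
    return pd.DataFrame(rows, columns=["cluster_id", "chrom", "strand",
                                       "motif_start", "acceptor_pos",
                                       "dominant_pos", "offset"])


def intersect_promoter_marks(regions: pd.DataFrame, start_sites,
                             up: int = 500, down: int = 100) -> np.ndarray:
    """Presence of an enriched mark around annotated start sites.

    ``regions`` has chrom/start/end (closed intervals);
    ``start_sites`` is an iterable of (chrom, strand, pos). The window
    is ``up`` bp upstream to ``down`` bp downstream of the start,
    strand-aware; any overlap of at least 1 bp counts as presence.
    """
    trees: dict[str, IntervalTree] = {}
    for _, r in regions.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()
                         ).addi(int(r["start"]), int(r["end"]) + 1, True)
    out = np.zeros(len(start_sites), dtype=bool)
    for i, (chrom, strand, pos) in enumerate(start_sites):
        if strand == "+":
            lo, hi = pos - up, pos + down
        else:
            lo, hi = pos - down, pos + up
        tree = trees.get(chrom)
        out[i] = bool(tree is not None and tree.overlap(lo, hi + 1))
    return out
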