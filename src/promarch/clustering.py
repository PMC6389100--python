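"""CTSS tag clustering, interquantile promoter widths and shape/CpG classes.

A tag cluster (TC) is a contiguous run of CTSSes on one chromosome and
strand within one sample. Following the standard CAGE pipeline, CTSSes
below 1 tpm are discarded, neighbouring retained CTSSes at most 20 bp
apart are merged, and single-CTSS clusters below 5 tpm are dropped. The
promoter width of a cluster is the genomic span between the positions
holding the 10th and 90th percentiles of its signal (interquantile
width, q0.1-q0.9), a shape measure robust to expression level; pooled
quartiles of these widths separate sharp from broad promoters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TagCluster:
    id: str
    stage: str | None
    chrom: str
    strand: str
    start: int
    end: int
    dominant_pos: int
    dominant_tpm: float
    total_tpm: float
    q_low: int = 0
    q_up: int = 0
    iq_width: int = 0
    shape_class: str | None = None
    cpg_class: str | None = None
    cpg_frequency: float | None = None
    positions: np.ndarray = field(default=None, repr=False)
    tpms: np.ndarray = field(default=None, repr=False)


def dominant_ctss(positions: np.ndarray, tpms: np.ndarray, strand: str
                  ) -> tuple[int, float]:
    """Position of maximal tpm; ties broken 5'-most on the strand."""
    positions = np.asarray(positions)
    tpms = np.asarray(tpms, dtype=float)
    best = tpms == tpms.max()
    cand = positions[best]
    if best.sum() > 1:
        logger.debug("dominant-CTSS tie among %d positions", best.sum())
    pos = cand.min() if strand == "+" else cand.max()
    return int(pos), float(tpms.max())


def interquantile_width(positions: np.ndarray, tpms: np.ndarray, strand: str,
                        q_lo: float = 0.1, q_hi: float = 0.9
                        ) -> tuple[int, int, int]:
    """Quantile positions and width of a cluster's signal.

    Walking the cluster 5'->3' on its strand, the lower quantile
    position is the first at which the cumulative tpm reaches
    ``q_lo * total`` and the upper the first at which it reaches
    ``q_hi * total``. Returned as genomic (q_low, q_up, width) with
    q_low <= q_up and width = q_up - q_low + 1 bp.
    """
    order = np.argsort(positions)
    if strand == "-":
        order = order[::-1]
    pos = np.asarray(positions)[order]
    cum = np.cumsum(np.asarray(tpms, dtype=float)[order])
    total = cum[-1]
    # tiny epsilon guards float round-off at exact quantile boundaries
    eps = 1e-9 * total
    i_lo = int(np.searchsorted(cum, q_lo * total - eps))
    i_hi = int(np.searchsorted(cum, q_hi * total - eps))
    a, b = int(pos[i_lo]), int(pos[i_hi])
    q_low, q_up = min(a, b), max(a, b)
    return q_low, q_up, q_up - q_low + 1


def cluster_ctss(table: pd.DataFrame, max_gap: int = 20,
                 min_ctss_tpm: float = 1.0, min_singleton_tpm: float = 5.0,
                 q_lo: float = 0.1, q_hi: float = 0.9) -> list[TagCluster]:
    """Cluster a normalised CTSS table into tag clusters.

    CTSSes with tpm < ``min_ctss_tpm`` are discarded before clustering;
    retained CTSSes on the same chromosome and strand merge into one
    cluster when consecutive positions are at most ``max_gap`` bp apart
    (single linkage); resulting single-CTSS clusters with tpm <
    ``min_singleton_tpm`` are dropped. Clusters never span a chromosome
    or strand boundary.
    """
    if "tpm" not in table.columns:
        raise ValueError("table must be tpm-normalised first (see normalize_tpm)")
    stage = table.attrs.get("stage")
    df = table[table["tpm"] >= min_ctss_tpm]
    clusters: list[TagCluster] = []
    cid = 0
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        tpm = grp["tpm"].to_numpy()[order]
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for seg_pos, seg_tpm in zip(np.split(pos, breaks), np.split(tpm, breaks)):
            if len(seg_pos) == 1 and seg_tpm[0] < min_singleton_tpm:
                continue
            cid += 1
            dom, dom_tpm = dominant_ctss(seg_pos, seg_tpm, strand)
            q_low, q_up, width = interquantile_width(
                seg_pos, seg_tpm, strand, q_lo, q_hi)
            clusters.append(TagCluster(
                id=f"tc{cid:05d}" + (f"_{stage}" if stage else ""),
                stage=stage, chrom=chrom, strand=strand,
                start=int(seg_pos[0]), end=int(seg_pos[-1]),
                dominant_pos=dom, dominant_tpm=dom_tpm,
                total_tpm=float(seg_tpm.sum()),
                q_low=q_low, q_up=q_up, iq_width=width,
                positions=seg_pos, tpms=seg_tpm,
            ))
    return clusters


def classify_shape(clusters: list[TagCluster]) -> None:
    """Assign sharp/intermediate/broad classes from pooled width quartiles.

    Quartiles of interquantile width are computed over the pooled
    cluster set (all stages together): width <= Q1 -> sharp,
    width >= Q3 -> broad, else intermediate. In the degenerate case
    Q1 >= Q3 (e.g. all widths identical) every cluster is classed
    intermediate. Mutates ``shape_class`` in place.
    """
    if not clusters:
        return
    widths = np.array([c.iq_width for c in clusters], dtype=float)
    q1, q3 = np.percentile(widths, [25, 75])
    if q1 >= q3:
        logger.info("degenerate width quartiles (Q1=Q3=%g): all intermediate", q1)
        for c in clusters:
            c.shape_class = "intermediate"
        return
    for c in clusters:
        if c.iq_width <= q1:
            c.shape_class = "sharp"
        elif c.iq_width >= q3:
            c.shape_class = "broad"
        else:
            c.shape_class = "intermediate"


def cpg_frequency(genome, chrom: str, center: int, window: int = 200) -> float:
    """CG-dinucleotide frequency in a window centred on `center`.

    The window covers ``window`` bases, offsets -window/2 .. window/2-1
    around the centre; the frequency is the CG count divided by
    (window - 1), the number of dinucleotide steps. CG content is
    strand-symmetric, so the plus strand is counted.
    """
    half = window // 2
    start = max(1, center - half)
    end = min(genome.length(chrom), center + half - 1)
    seq = genome.fetch(chrom, start, end, "+")
    count = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    return count / (window - 1)


def classify_cpg(clusters: list[TagCluster], genome, window: int = 200) -> None:
    """Assign LCG/mid/HCG classes from pooled CpG-frequency quartiles.

    CpG frequency is measured in a ``window`` bp window centred on each
    cluster's dominant CTSS; the upper quartile of the pooled set is
    classed HCG, the lower quartile LCG. Mutates clusters in place.
    """
    if not clusters:
        return
    freqs = np.array([
        cpg_frequency(genome, c.chrom, c.dominant_pos, window) for c in clusters
    ])
    q1, q3 = np.percentile(freqs, [25, 75])
    for c, f in zip(clusters, freqs):
        c.cpg_frequency = float(f)
        if q1 >= q3:
            c.cpg_class = "mid"
        elif f <= q1:
            c.cpg_class = "LCG"
        elif f >= q3:
            c.cpg_class = "HCG"
        else:
            c.cpg_class = "mid"


def clusters_to_frame(clusters: list[TagCluster]) -> pd.DataFrame:
    """Flatten tag clusters to a plot/export-ready table."""
    cols = ["id", "stage", "chrom", "strand", "start", "end", "dominant_pos",
            "dominant_tpm", "total_tpm", "q_low", "q_up", "iq_width",
            "shape_class", "cpg_class", "cpg_frequency"]
    return pd.DataFrame([{k: getattr(c, k) for k in cols} for c in clusters])
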