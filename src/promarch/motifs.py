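"""Position-specific core-promoter motif analysis around dominant TSSs.

All analyses work on strand-oriented promoter windows centred on the
dominant CTSS (minus-strand promoters are reverse complemented), with
offsets measured from a motif's 5'-most base to the TSS: positive =
upstream, 0 = the TSS itself. Fixed search windows quoted as e.g.
"37-22 bp upstream" are closed intervals of that offset, [22, 37].

Four complementary scans are provided: exhaustive k-mer positional
enrichment (k = 1-6) against a per-sequence composition null, IUPAC
consensus searches in fixed upstream windows (TATA-type elements,
TCTAGA, ACCATAA), per-position dinucleotide profiles, and position
weight matrix scanning of the 101 bp upstream region at a relative
score threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def iupac_matches(motif_letter: str, base: str) -> bool:
    return base in ambiguous_dna_values.get(motif_letter.upper(), "")


def _match_at(seq: str, i: int, motif: str) -> bool:
    if i < 0 or i + len(motif) > len(seq):
        return False
    return all(iupac_matches(m, seq[i + j]) for j, m in enumerate(motif))


def extract_windows(genome, promoters, flank: int = 100
                    ) -> tuple[list[str], int, list]:
    """Strand-oriented windows of 2*flank bp centred on dominant CTSSs.

    ``promoters`` is an iterable of objects with chrom/strand and a
    dominant position (TagCluster ``dominant_pos`` or a (chrom, strand,
    pos[, id]) tuple). Returns (sequences, center_index, ids): in every
    sequence, index ``center_index`` is the dominant TSS, so a motif
    starting at index i sits at offset ``center_index - i`` (positive =
    upstream). Promoters whose window runs off the chromosome are
    dropped with a log message.
    """
    seqs, ids = [], []
    for p in promoters:
        if isinstance(p, tuple):
            chrom, strand, pos = p[:3]
            pid = p[3] if len(p) > 3 else f"{chrom}:{pos}{strand}"
        else:
            chrom, strand, pos, pid = p.chrom, p.strand, p.dominant_pos, p.id
        if strand == "+":
            start, end = pos - flank, pos + flank - 1
        else:
            start, end = pos - flank + 1, pos + flank
        if start < 1 or end > genome.length(chrom):
            logger.info("window off chromosome for %s, dropped", pid)
            continue
        seqs.append(genome.fetch(chrom, start, end, strand))
        ids.append(pid)
    return seqs, flank, ids


# ---------------------------------------------------------------------------
# exhaustive k-mer positional enrichment
# ---------------------------------------------------------------------------

@dataclass
class KmerScan:
    k: int
    offsets: np.ndarray                 # offset of each scan position
    counts: dict                        # kmer -> occurrence count per offset
    expected: dict                      # kmer -> expected count (flat)
    ranking: pd.DataFrame               # kmer, peak_offset, peak_enrichment


def scan_kmers(seqs: list[str], center: int, k_range=range(1, 7)
               ) -> dict[int, KmerScan]:
    """Positional occurrence and enrichment of every k-mer, k in k_range.

    Counts the occurrences of each k-mer at every offset across the
    promoter set. The expected count per offset is the sum over
    sequences of the product of that sequence's own mononucleotide
    frequencies over the k-mer's letters (a composition null that
    controls GC skew); enrichment = observed / expected, and k-mers are
    ranked by their peak positional enrichment. Sequences containing N
    are skipped entirely (logged).
    """
    clean = [s.upper() for s in seqs if "N" not in s.upper()]
    if len(clean) < len(seqs):
        logger.warning("scan_kmers: %d windows with N skipped",
                       len(seqs) - len(clean))
    if not clean:
        raise ValueError("no N-free windows to scan")
    length = len(clean[0])
    if any(len(s) != length for s in clean):
        raise ValueError("windows must have equal length")

    comps = np.array([[s.count(b) / length for b in _BASES] for s in clean])
    out: dict[int, KmerScan] = {}
    for k in k_range:
        n_pos = length - k + 1
        offsets = center - np.arange(n_pos)
        counts: dict[str, np.ndarray] = {}
        for s in clean:
            for i in range(n_pos):
                kmer = s[i : i + k]
                arr = counts.get(kmer)
                if arr is None:
                    arr = counts[kmer] = np.zeros(n_pos)
                arr[i] += 1
        expected = {}
        rank_rows = []
        for kmer, arr in counts.items():
            idx = [_BASE_INDEX[b] for b in kmer]
            exp = float(comps[:, idx].prod(axis=1).sum())
            expected[kmer] = exp
            enr = arr / exp if exp > 0 else np.zeros_like(arr)
            j = int(np.argmax(enr))
            rank_rows.append({"kmer": kmer, "peak_offset": int(offsets[j]),
                              "peak_count": int(arr[j]),
                              "peak_enrichment": float(enr[j])})
        ranking = (pd.DataFrame(rank_rows)
                   .sort_values("peak_enrichment", ascending=False)
                   .reset_index(drop=True))
        out[k] = KmerScan(k, offsets, counts, expected, ranking)
    return out


# ---------------------------------------------------------------------------
# fixed-window IUPAC search
# ---------------------------------------------------------------------------

def search_fixed_window(seqs: list[str], center: int, motif: str,
                        window: tuple[int, int], ids=None
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """IUPAC motif search in a fixed upstream window.

    ``window = (lo, hi)`` restricts the motif 5'-base offset to the
    closed interval [lo, hi] (e.g. the TATA window "37-22 bp upstream"
    is (22, 37)). Returns (hits table with promoter/offset per match,
    boolean per-promoter presence array).
    """
    lo, hi = min(window), max(window)
    if ids is None:
        ids = list(range(len(seqs)))
    rows = []
    present = np.zeros(len(seqs), dtype=bool)
    for si, (s, pid) in enumerate(zip(seqs, ids)):
        s = s.upper()
        for off in range(lo, hi + 1):
            if _match_at(s, center - off, motif):
                rows.append({"promoter": pid, "motif": motif, "offset": off,
                             "score": 1.0})
                present[si] = True
    return pd.DataFrame(rows, columns=["promoter", "motif", "offset", "score"]), present


def motif_offsets(seqs: list[str], center: int, motif: str,
                  window: tuple[int, int], ids=None) -> pd.Series:
    """Offset of the most-upstream hit per promoter (NaN when absent)."""
    hits, _ = search_fixed_window(seqs, center, motif, window, ids)
    if hits.empty:
        return pd.Series(dtype=float)
    return hits.groupby("promoter")["offset"].max()


def positional_density(seqs: list[str], center: int, motif: str,
                       order_by: np.ndarray | None = None) -> pd.DataFrame:
    """Indicator matrix of motif starts: rows = promoters, cols = offsets.

    Column 0 is the dominant TSS. ``order_by`` (e.g. interquantile
    widths) sorts the rows broad-to-sharp for heatmap display.
    """
    length = len(seqs[0])
    n_pos = length - len(motif) + 1
    offsets = center - np.arange(n_pos)
    mat = np.zeros((len(seqs), n_pos), dtype=int)
    for si, s in enumerate(seqs):
        s = s.upper()
        for i in range(n_pos):
            if _match_at(s, i, motif):
                mat[si, i] = 1
    df = pd.DataFrame(mat, columns=offsets)
    if order_by is not None:
        df = df.iloc[np.argsort(-np.asarray(order_by))]
    return df


# ---------------------------------------------------------------------------
# dinucleotide profile
# ---------------------------------------------------------------------------

def dinucleotide_profile(seqs: list[str], center: int) -> pd.DataFrame:
    """Frequency of each of the 16 dinucleotides at each offset.

    Rows are dinucleotides, columns are offsets of the dinucleotide's
    first base relative to the dominant TSS; each column sums to 1 over
    the sequences informative (N-free) at that position.
    """
    dinucs = [a + b for a in _BASES for b in _BASES]
    length = len(seqs[0])
    n_pos = length - 1
    offsets = center - np.arange(n_pos)
    mat = np.zeros((16, n_pos))
    informative = np.zeros(n_pos)
    index = {d: i for i, d in enumerate(dinucs)}
    for s in seqs:
        s = s.upper()
        for i in range(n_pos):
            d = s[i : i + 2]
            if d in index:
                mat[index[d], i] += 1
                informative[i] += 1
    informative[informative == 0] = 1.0
    return pd.DataFrame(mat / informative, index=dinucs, columns=offsets)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_NEG_INF = -1e9  # finite stand-in for log(0): keeps score arithmetic finite


def pwm_from_counts(counts: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Column-probability PWM from a (L, 4) count matrix (columns ACGT)."""
    counts = np.asarray(counts, dtype=float) + pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def read_meme_minimal(path) -> dict[str, np.ndarray]:
    """Read PWMs from a MEME minimal-format motif file."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = {}
    for m in records:
        pwm = np.column_stack([np.asarray(m.pwm[b]) for b in _BASES])
        out[m.name] = pwm
    return out


def pwm_scan(seqs: list[str], center: int, pwm: np.ndarray,
             upstream_len: int = 101, min_rel_score: float = 0.85,
             ids=None) -> pd.DataFrame:
    """Scan the upstream region with a PWM at a relative-score threshold.

    Scores each placement of the matrix inside the ``upstream_len`` bp
    immediately upstream of the dominant TSS (motif fully within
    offsets [1, upstream_len]) on the oriented strand. The score is the
    sum of log-odds column scores against a uniform background, reported
    relative to the matrix's score range: (S - S_min)/(S_max - S_min).
    Hits with relative score >= ``min_rel_score`` are returned.
    """
    pwm = np.asarray(pwm, dtype=float)
    L = pwm.shape[0]
    with np.errstate(divide="ignore"):
        W = np.log2(pwm / 0.25)
    W[~np.isfinite(W)] = _NEG_INF
    s_min, s_max = W.min(axis=1).sum(), W.max(axis=1).sum()
    span = s_max - s_min
    if ids is None:
        ids = list(range(len(seqs)))
    rows = []
    for s, pid in zip(seqs, ids):
        s = s.upper()
        for off in range(L, upstream_len + 1):
            i = center - off
            if i < 0 or i + L > len(s):
                continue
            window = s[i : i + L]
            if "N" in window:
                continue
            score = sum(W[j, _BASE_INDEX[b]] for j, b in enumerate(window))
            rel = (score - s_min) / span if span > 0 else 1.0
            if rel >= min_rel_score:
                rows.append({"promoter": pid, "offset": off,
                             "score": float(rel)})
    return pd.DataFrame(rows, columns=["promoter", "offset", "score"])


# ---------------------------------------------------------------------------
# motif x expression-class association
# ---------------------------------------------------------------------------

def chi_square_independence(table: np.ndarray, correction: bool = False
                            ) -> tuple[float, int, float]:
    """Chi-square test of independence; Yates correction off by default."""
    stat, p, dof, _ = chi2_contingency(np.asarray(table), correction=correction)
    return float(stat), int(dof), float(p)


def motif_expression_association(has_motif: pd.Series, som_units: pd.Series,
                                 correction: bool = False) -> dict:
    """Cross-tabulate motif presence against SOM expression classes.

    Both inputs are indexed by promoter id (aligned on the
    intersection). Returns percentages in both directions -- per class:
    % of its promoters containing the motif; per motif: % of
    motif-containing promoters falling in each class -- plus a
    chi-square test of association (statistic, df, p; no Yates
    correction by default).
    """
    idx = has_motif.index.intersection(som_units.index)
    hm = has_motif.loc[idx].astype(bool)
    su = som_units.loc[idx]
    tab = pd.crosstab(su, hm).reindex(columns=[False, True], fill_value=0)
    pct_of_class = 100.0 * tab[True] / tab.sum(axis=1)
    total_with = tab[True].sum()
    pct_of_motif = (100.0 * tab[True] / total_with) if total_with else tab[True] * 0.0
    if total_with == 0 or tab[False].sum() == 0:
        # degenerate table (motif everywhere or nowhere): no association testable
        stat, dof, p = 0.0, 0, 1.0
    else:
        stat, dof, p = chi_square_independence(tab.to_numpy(), correction)
    return {
        "pct_of_class_with_motif": pct_of_class,
        "pct_of_motif_by_class": pct_of_motif,
        "table": tab,
        "chi2": stat, "df": dof, "p_value": p,
    }
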