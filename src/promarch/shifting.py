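"""Promoter shifting between developmental stages.

A consensus promoter "shifts" between two samples when the bulk of its
transcription initiation relocates along the genome. The shifting score
compares the 5'->3' cumulative initiation fractions of the two samples
within the consensus region: it is the largest vertical gap between the
two cumulative curves, i.e. the fraction of the lower-expressed
sample's initiation occurring upstream (or downstream) of the other
sample's initiation. Significance comes from a two-sample
Kolmogorov-Smirnov test on the same cumulative distributions with
effective sample sizes taken from raw tag counts, followed by
Benjamini-Hochberg FDR control across promoters. A shift is called at
score > 0.6 and FDR < 0.01.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ShiftResult:
    consensus_id: str
    stage_a: str
    stage_b: str
    shifting_score: float
    direction: str
    ks_statistic: float
    p_value: float
    fdr: float
    is_shift: bool
    tc_overlap: float | None = None


def _cumulative_fractions(sig_a: pd.Series, sig_b: pd.Series, strand: str
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fractions of both signals on the union position grid,
    walked 5'->3' on the given strand; each normalised to 1."""
    pos = np.union1d(sig_a.index.to_numpy(), sig_b.index.to_numpy())
    if strand == "-":
        pos = pos[::-1]
    a = sig_a.reindex(pos, fill_value=0.0).to_numpy(dtype=float)
    b = sig_b.reindex(pos, fill_value=0.0).to_numpy(dtype=float)
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("shifting score undefined for zero signal")
    return np.cumsum(a) / ta, np.cumsum(b) / tb


def shifting_score(sig_a: pd.Series, sig_b: pd.Series, strand: str = "+"
                   ) -> tuple[float, str]:
    """Shifting score in [0, 1] and shift direction.

    ``sig_a``/``sig_b`` map genomic position -> signal (tpm) within one
    consensus region. Let L be the sample with the lower total signal
    and H the other; with F_L, F_H their 5'->3' cumulative fractions the
    score is max over positions of |F_L - F_H|, read as the fraction of
    L's initiation lying upstream ("upstream", when F_L leads) or
    downstream ("downstream", when F_H leads) of H's initiation.
    """
    if sig_a.sum() <= sig_b.sum():
        lo, hi = sig_a, sig_b
    else:
        lo, hi = sig_b, sig_a
    f_l, f_h = _cumulative_fractions(lo, hi, strand)
    diff = f_l - f_h
    i = int(np.argmax(np.abs(diff)))
    score = float(abs(diff[i]))
    direction = "upstream" if diff[i] >= 0 else "downstream"
    return score, direction


def ks_shift_test(sig_a: pd.Series, sig_b: pd.Series,
                  n_eff_a: float, n_eff_b: float, strand: str = "+"
                  ) -> tuple[float, float]:
    """Two-sample KS test on tpm-weighted positional distributions.

    The statistic is the maximum absolute difference of the cumulative
    fractions; the p-value comes from the asymptotic KS distribution
    with effective size n_a*n_b/(n_a+n_b), where the n are raw
    (un-normalised) tag counts in the region. Asymptotics are flagged
    when the effective size drops below 10.
    """
    if n_eff_a <= 0 or n_eff_b <= 0:
        raise ValueError("effective sample sizes must be positive")
    f_a, f_b = _cumulative_fractions(sig_a, sig_b, strand)
    d = float(np.max(np.abs(f_a - f_b)))
    n_eff = n_eff_a * n_eff_b / (n_eff_a + n_eff_b)
    if n_eff < 10:
        logger.warning("KS effective size %.1f < 10: asymptotic p unreliable",
                       n_eff)
    p = float(kolmogorov(np.sqrt(n_eff) * d))
    return d, min(1.0, p)


def _region_signal(table: pd.DataFrame, chrom: str, strand: str,
                   start: int, end: int) -> tuple[pd.Series, float]:
    """tpm per position and total raw count within a closed interval."""
    m = ((table["chrom"] == chrom) & (table["strand"] == strand)
         & (table["pos"] >= start) & (table["pos"] <= end))
    sub = table[m]
    return (pd.Series(sub["tpm"].to_numpy(), index=sub["pos"].to_numpy()),
            float(sub["count"].sum()))


def _tc_overlap(cp, stage_a: str, stage_b: str) -> float | None:
    """Fractional overlap of the two stages' interquantile intervals
    (intersection over the shorter interval)."""
    best = {}
    for stage, c in cp.members:
        if stage in (stage_a, stage_b):
            if stage not in best or c.total_tpm > best[stage].total_tpm:
                best[stage] = c
    if stage_a not in best or stage_b not in best:
        return None
    a, b = best[stage_a], best[stage_b]
    inter = min(a.q_up, b.q_up) - max(a.q_low, b.q_low) + 1
    shorter = min(a.iq_width, b.iq_width)
    return max(0.0, inter / shorter)


def detect_shifts(consensus, tables_by_stage: dict[str, pd.DataFrame],
                  stage_a: str, stage_b: str,
                  score_min: float = 0.6, fdr_max: float = 0.01
                  ) -> pd.DataFrame:
    """Score every consensus promoter for a shift between two stages.

    Promoters with zero signal in either stage are skipped (logged).
    Returns one row per tested promoter with the shifting score,
    direction, KS statistic, BH-adjusted FDR, the shift call
    (score > ``score_min`` and FDR < ``fdr_max``) and the fractional
    overlap of the two stages' tag-cluster interquantile intervals.
    """
    ta, tb = tables_by_stage[stage_a], tables_by_stage[stage_b]
    rows = []
    skipped = 0
    for cp in consensus:
        sig_a, n_a = _region_signal(ta, cp.chrom, cp.strand, cp.start, cp.end)
        sig_b, n_b = _region_signal(tb, cp.chrom, cp.strand, cp.start, cp.end)
        if sig_a.sum() <= 0 or sig_b.sum() <= 0:
            skipped += 1
            continue
        score, direction = shifting_score(sig_a, sig_b, cp.strand)
        ks, p = ks_shift_test(sig_a, sig_b, n_a, n_b, cp.strand)
        rows.append(ShiftResult(cp.id, stage_a, stage_b, score, direction,
                                ks, p, np.nan, False,
                                _tc_overlap(cp, stage_a, stage_b)))
    if skipped:
        logger.info("detect_shifts %s vs %s: %d promoters skipped (zero signal)",
                    stage_a, stage_b, skipped)
    if not rows:
        return pd.DataFrame(columns=[f.name for f in
                                     ShiftResult.__dataclass_fields__.values()])
    pvals = np.array([r.p_value for r in rows])
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(rows, fdr):
        r.fdr = float(q)
        r.is_shift = bool(r.shifting_score > score_min and r.fdr < fdr_max)
    return pd.DataFrame([vars(r) for r in rows])


def pairwise_shift_counts(consensus, tables_by_stage: dict[str, pd.DataFrame],
                          stages=None, score_min: float = 0.6,
                          fdr_max: float = 0.01) -> pd.DataFrame:
    """Number of shifting promoters for every stage pair.

    Returns a long-form table (stage_a, stage_b, n_tested, n_shifts,
    n_upstream, n_downstream); pivot on (stage_a, stage_b) for the
    heatmap-style matrix.
    """
    stages = list(tables_by_stage) if stages is None else list(stages)
    rows = []
    for a, b in itertools.combinations(stages, 2):
        res = detect_shifts(consensus, tables_by_stage, a, b,
                            score_min, fdr_max)
        hits = res[res["is_shift"]]
        rows.append({
            "stage_a": a, "stage_b": b, "n_tested": len(res),
            "n_shifts": len(hits),
            "n_upstream": int((hits["direction"] == "upstream").sum()),
            "n_downstream": int((hits["direction"] == "downstream").sum()),
        })
    return pd.DataFrame(rows)
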