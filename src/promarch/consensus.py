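"""Cross-stage consensus promoter regions.

Tag clusters above an expression floor are represented by their
interquantile intervals [q0.1, q0.9] and merged across stages on the
same chromosome and strand whenever the gap between intervals is at
most 100 bp, yielding one consensus promoter region per initiation
locus with a per-stage expression vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clustering import TagCluster
from .synthetic import STAGES


@dataclass
class ConsensusPromoter:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    tpm: dict                     # stage -> summed member tpm
    dominant: dict                # stage -> dominant CTSS position (or None)
    iq_width: dict                # stage -> member-cluster iq width (or None)
    som_unit: str | None = None
    members: list = field(default_factory=list)  # (stage, TagCluster)

    def tpm_vector(self, stages=STAGES) -> list[float]:
        return [self.tpm.get(s, 0.0) for s in stages]


def build_consensus(clusters_by_stage: dict[str, list[TagCluster]],
                    min_tpm: float = 5.0,
                    merge_dist: int = 100) -> list[ConsensusPromoter]:
    """Merge per-stage tag clusters into consensus promoter regions.

    Clusters with total tpm > ``min_tpm`` enter the merge as their
    [q_low, q_up] intervals; intervals on the same chromosome and strand
    merge when the gap between them (bp strictly between the intervals)
    is at most ``merge_dist``. The consensus span is the union of merged
    intervals; per-stage tpm is the sum over member clusters, and the
    per-stage dominant position / width are taken from the
    highest-expressed member cluster of that stage.
    """
    entries = []
    for stage, clusters in clusters_by_stage.items():
        for c in clusters:
            if c.total_tpm > min_tpm:
                entries.append((c.chrom, c.strand, c.q_low, c.q_up, stage, c))
    entries.sort(key=lambda e: (e[0], e[1], e[2], e[3]))

    out: list[ConsensusPromoter] = []
    group: list = []
    cur_key = None
    cur_end = None

    def flush():
        if not group:
            return
        chrom, strand = group[0][0], group[0][1]
        start = min(e[2] for e in group)
        end = max(e[3] for e in group)
        tpm: dict[str, float] = {}
        best: dict[str, TagCluster] = {}
        for _, _, _, _, stage, c in group:
            tpm[stage] = tpm.get(stage, 0.0) + c.total_tpm
            if stage not in best or c.total_tpm > best[stage].total_tpm:
                best[stage] = c
        out.append(ConsensusPromoter(
            id=f"cp{len(out) + 1:05d}", chrom=chrom, strand=strand,
            start=start, end=end, tpm=tpm,
            dominant={s: c.dominant_pos for s, c in best.items()},
            iq_width={s: c.iq_width for s, c in best.items()},
            members=[(e[4], e[5]) for e in group],
        ))

    for e in entries:
        key = (e[0], e[1])
        if cur_key == key and e[2] - cur_end - 1 <= merge_dist:
            group.append(e)
            cur_end = max(cur_end, e[3])
        else:
            flush()
            group = [e]
            cur_key, cur_end = key, e[3]
    flush()
    return out


def consensus_to_frame(consensus: list[ConsensusPromoter],
                       stages=STAGES) -> pd.DataFrame:
    rows = []
    for cp in consensus:
        row = {"id": cp.id, "chrom": cp.chrom, "strand": cp.strand,
               "start": cp.start, "end": cp.end, "som_unit": cp.som_unit}
        for s in stages:
            row[f"tpm_{s}"] = cp.tpm.get(s, 0.0)
            row[f"dominant_{s}"] = cp.dominant.get(s)
        rows.append(row)
    return pd.DataFrame(rows)
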