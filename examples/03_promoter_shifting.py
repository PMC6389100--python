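"""Promoter-shift detection between two developmental stages.

Constructs 100 consensus promoters of which 10 initiate from a block
300 bp downstream in the second sample, then scores every promoter
(shifting score = largest gap between the two cumulative initiation
curves) and calls shifts at score > 0.6 and Benjamini-Hochberg
FDR < 0.01. Expect the 10 planted shifts called with none of the
unshifted promoters.
"""

import numpy as np
import pandas as pd

import promarch as pa

rng = np.random.default_rng(0)
rows_a, rows_b, cons = [], [], []
for i in range(100):
    base = 2000 * i + 500
    shifted = i < 10
    block_a = base + rng.integers(0, 5, 300)
    block_b = (base + 300 if shifted else base) + rng.integers(0, 5, 300)
    for pos, cnt in zip(*np.unique(block_a, return_counts=True)):
        rows_a.append(("chr1", int(pos), "+", int(cnt)))
    for pos, cnt in zip(*np.unique(block_b, return_counts=True)):
        rows_b.append(("chr1", int(pos), "+", int(cnt)))
    cons.append(pa.ConsensusPromoter(
        id=f"cp{i:03d}", chrom="chr1", strand="+", start=base - 50,
        end=base + 400, tpm={}, dominant={}, iq_width={}, members=[]))

cols = ["chrom", "pos", "strand", "count"]
tables = {"tailbud": pa.normalize_tpm(pd.DataFrame(rows_a, columns=cols)),
          "male": pa.normalize_tpm(pd.DataFrame(rows_b, columns=cols))}

res = pa.detect_shifts(cons, tables, "tailbud", "male")
hits = res[res["is_shift"]]
print(f"tested {len(res)} promoters, called {len(hits)} shifts")
print(hits[["consensus_id", "shifting_score", "direction", "fdr"]]
      .to_string(index=False))
print("\nplanted shifts were cp000..cp009; a score of 1.0 means all of the"
      "\nlower-expressed sample's initiation lies beyond the other sample's.")
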