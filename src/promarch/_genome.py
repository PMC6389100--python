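"""In-memory genome with 1-based, fully-closed coordinates.

All public functions in this package address the genome the way genome
browsers and GFF3 do: position 1 is the first base and intervals include
both endpoints. Strand-aware fetches return the reverse complement for
the minus strand, so the returned string always reads 5'->3' on the
requested strand.
"""

from __future__ import annotations

from collections.abc import Mapping
from typing import Iterator

from Bio.Seq import reverse_complement


class Genome(Mapping):
    """Mutable dictionary of chromosome sequences.

    Parameters
    ----------
    seqs
        Mapping of chromosome name to sequence (str or bytearray).
        Sequences are stored as bytearrays so motifs can be planted
        in place.
    """

    def __init__(self, seqs: Mapping[str, str | bytes | bytearray]):
        self._seqs: dict[str, bytearray] = {
            name: bytearray(s.encode() if isinstance(s, str) else s)
            for name, s in seqs.items()
        }

    # Mapping interface ------------------------------------------------
    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom].decode()

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    # Sequence access --------------------------------------------------
    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of the closed interval [start, end].

        For strand "-" the reverse complement is returned, i.e. the
        sequence reads 5'->3' on the minus strand.
        """
        if start < 1 or end > len(self._seqs[chrom]) or start > end:
            raise ValueError(
                f"invalid interval {chrom}:{start}-{end} "
                f"(chrom length {len(self._seqs[chrom])})"
            )
        seq = self._seqs[chrom][start - 1 : end].decode()
        return reverse_complement(seq) if strand == "-" else seq

    def plant(self, chrom: str, pos5: int, strand: str, seq: str) -> tuple[int, int]:
        """Write `seq` into the genome with its 5'-most base at `pos5`.

        On "+" the motif occupies [pos5, pos5+len-1]; on "-" it occupies
        [pos5-len+1, pos5] and the stored plus-strand bases are the
        reverse complement. Returns the genomic (start, end) occupied.
        """
        n = len(seq)
        if strand == "+":
            start, end = pos5, pos5 + n - 1
            insert = seq
        else:
            start, end = pos5 - n + 1, pos5
            insert = reverse_complement(seq)
        if start < 1 or end > len(self._seqs[chrom]):
            raise ValueError(f"plant out of bounds: {chrom}:{start}-{end}")
        self._seqs[chrom][start - 1 : end] = insert.encode()
        return start, end

    # I/O ---------------------------------------------------------------
    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self:
                fh.write(f">{name}\n")
                s = self[name]
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")})
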