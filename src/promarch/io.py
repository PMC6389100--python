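"""Readers and writers for CTSS, annotation, SL-site and probe tables.

CTSS tables are 4-column TSVs (chrom, 1-based position, strand, raw tag
count), one file per developmental stage. Counts are normalised to tags
per million (tpm) against a library size, which defaults to the table's
own total when the mapped-library total is not supplied.
"""

from __future__ import annotations

import logging
import tempfile
from pathlib import Path

import pandas as pd

from ._genome import Genome

logger = logging.getLogger(__name__)

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]


class CtssFormatError(ValueError):
    """A CTSS table row violates the dialect (bad position/strand/count)."""


def read_ctss(path, stage_label: str | None = None) -> pd.DataFrame:
    """Read a 4-column CTSS TSV into a DataFrame.

    Malformed rows raise :class:`CtssFormatError` naming the offending
    1-based line number. Duplicate (chrom, pos, strand) keys are summed
    with a logged warning. The stage label is attached as
    ``df.attrs["stage"]``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=CTSS_COLUMNS,
                     dtype=str, comment="#")
    for col, caster, check in (
        ("pos", int, lambda v: v > 0),
        ("count", int, lambda v: v >= 0),
        ("strand", str, lambda v: v in ("+", "-")),
    ):
        for line0, raw in df[col].items():
            try:
                val = caster(raw)
                ok = check(val)
            except (TypeError, ValueError):
                ok = False
            if not ok:
                raise CtssFormatError(
                    f"{path.name} line {line0 + 1}: invalid {col} {raw!r}")
    df["pos"] = df["pos"].astype(int)
    df["count"] = df["count"].astype(int)
    n_dup = len(df) - df.groupby(["chrom", "pos", "strand"]).ngroups
    if n_dup:
        logger.warning("%s: %d duplicate CTSS keys summed", path.name, n_dup)
        df = df.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
    df = df.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)
    df.attrs["stage"] = stage_label
    return df


def write_ctss(df: pd.DataFrame, path) -> None:
    df[CTSS_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def normalize_tpm(df: pd.DataFrame, library_size: int | None = None) -> pd.DataFrame:
    """Return a copy with a ``tpm`` column: count * 1e6 / library size.

    ``library_size`` defaults to the table's total count (in which case
    the tpm column sums to exactly one million); pass the mapped-library
    total when it is known. Raw counts are unchanged.
    """
    if len(df) == 0:
        raise ValueError("cannot normalize an empty CTSS table")
    total = int(df["count"].sum()) if library_size is None else int(library_size)
    if total <= 0:
        raise ValueError("library size must be positive")
    out = df.copy()
    out["tpm"] = out["count"] * 1e6 / total
    out.attrs.update(df.attrs)
    out.attrs["library_size"] = total
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write a gene table as GFF3 with operon_id/operon_pos attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = [f"ID={g['gene_id']}"]
            if g.get("operon_id"):
                attrs.append(f"operon_id={g['operon_id']}")
                attrs.append(f"operon_pos={int(g['operon_pos'])}")
            fh.write("\t".join([
                g["chrom"], "promarch", "gene", str(int(g["start"])),
                str(int(g["end"])), ".", g["strand"], ".", ";".join(attrs),
            ]) + "\n")


def read_gff3(path) -> pd.DataFrame:
    """Read gene models from GFF3, honouring operon_id/operon_pos attributes."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        op = feat.attributes.get("operon_id", [None])[0]
        rows.append({
            "gene_id": feat.id, "chrom": feat.seqid,
            "start": feat.start, "end": feat.end, "strand": feat.strand,
            "operon_id": op,
            "operon_pos": int(feat.attributes.get("operon_pos", [0])[0]) if op else 0,
        })
    return (pd.DataFrame(rows)
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def read_fasta(path) -> Genome:
    return Genome.from_fasta(path)


# ---------------------------------------------------------------------------
# SL sites and probes: plain TSVs with headers
# ---------------------------------------------------------------------------

def read_sl_sites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sl_sites(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_probes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_probes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def roundtrip_ok(df: pd.DataFrame) -> bool:
    """Write a CTSS table to a temp file, read it back, compare exactly."""
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        name = fh.name
    try:
        write_ctss(df, name)
        back = read_ctss(name)
        a = df[CTSS_COLUMNS].reset_index(drop=True)
        return a.equals(back[CTSS_COLUMNS])
    finally:
        Path(name).unlink(missing_ok=True)
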