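"""Synthetic CAGE study generator with planted, machine-readable ground truth.

Emulates a compact marine-chordate genome sampled at six developmental
stages (oocyte, tailbud, tadpole, juvenile day 2, adult female, adult
male): a multi-chromosome genome with a stated fraction of genes grouped
into operons, promoters planted from archetypes (sharp promoters with a
core motif at a fixed upstream offset, broad promoters with dispersed
initiation), per-stage CTSS count tables, spliced-leader (SL)
trans-splice acceptor sites with an AG dinucleotide immediately
upstream, and two-channel tiling-array probes with nucleosome-phased
signal around broad promoters.

Every emitted tag, motif and SL site is recorded in a :class:`GroundTruth`
object, so downstream recovery (clustering, shape classes, motif offsets,
shift detection, SL exclusion) can be audited exactly.

Coordinates are 1-based and fully closed. Motif offsets are measured
from the motif's 5'-most base to the dominant TSS, strand-aware, with
positive values upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._genome import Genome

#: Developmental stages of the six CAGE libraries, in life-cycle order.
STAGES = ("oocyte", "tailbud", "tadpole", "day2", "female", "male")


class PlacementError(RuntimeError):
    """Raised when a motif cannot be planted without colliding with a prior edit."""


@dataclass(frozen=True)
class PromoterArchetype:
    """Template for a class of planted promoters.

    Attributes
    ----------
    id : str
        Archetype label, e.g. ``"male_sharp"``.
    shape : {"sharp", "broad"}
        Sharp promoters emit >=90% of tags within +/-2 bp of the dominant
        TSS; broad promoters emit from a discretised normal.
    motif : str or None
        Core-promoter motif planted upstream of the TSS (plain ACGT).
    motif_offset : int
        Distance in bp from the motif's 5' base to the dominant TSS,
        strand-aware, positive upstream. Required when ``motif`` is set.
    stage_profile : tuple of 6 floats
        Relative expression weight in each of the six stages.
    spread_sd : float
        Dispersion (bp) of initiation positions; <=1 for sharp, >=5 for
        broad.
    """

    id: str
    shape: str
    motif: str | None = None
    motif_offset: int = 0
    stage_profile: tuple[float, ...] = (1.0,) * 6
    spread_sd: float = 0.0

    def __post_init__(self):
        if self.shape not in ("sharp", "broad"):
            raise ValueError(f"shape must be sharp|broad, got {self.shape!r}")
        if self.motif is not None:
            if self.motif_offset <= 0:
                raise ValueError("motif_offset must be > 0 when a motif is set")
            if set(self.motif) - set("ACGT"):
                raise ValueError("motif must be over {A,C,G,T}")
        if len(self.stage_profile) != len(STAGES):
            raise ValueError(f"stage_profile must have {len(STAGES)} entries")
        if not any(w > 0 for w in self.stage_profile):
            raise ValueError("stage_profile needs at least one positive entry")
        if any(w < 0 for w in self.stage_profile):
            raise ValueError("stage_profile weights must be non-negative")
        if self.shape == "sharp" and self.spread_sd > 1:
            raise ValueError("sharp archetypes require spread_sd <= 1")
        if self.shape == "broad" and self.spread_sd < 5:
            raise ValueError("broad archetypes require spread_sd >= 5")


@dataclass
class PlantedPromoter:
    """One planted promoter instance and everything true about it."""

    id: str
    archetype_id: str
    shape: str
    chrom: str
    strand: str
    tss: int                      # true dominant TSS (same in every stage)
    stage_profile: tuple[float, ...]
    spread_sd: float
    gene_id: str | None = None
    operon_internal: bool = False
    motif: str | None = None
    motif_offset: int = 0
    motif_start: int | None = None  # genomic position of the motif 5' base
    sl_sites: list = field(default_factory=list)  # (chrom, pos, strand, count)
    sl_exclusion: bool = False    # acceptor AG coincides with motif AG


@dataclass
class GroundTruth:
    """Planted truth for a synthetic study: promoters keyed by id."""

    promoters: dict = field(default_factory=dict)

    def add(self, p: PlantedPromoter) -> None:
        self.promoters[p.id] = p

    def by_archetype(self, archetype_id: str) -> list[PlantedPromoter]:
        return [p for p in self.promoters.values() if p.archetype_id == archetype_id]

    def to_json(self, path) -> None:
        def _plain(o):
            if isinstance(o, np.bool_):
                return bool(o)
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            raise TypeError(f"not JSON-serialisable: {type(o)}")

        with open(path, "w") as fh:
            json.dump({k: asdict(v) for k, v in self.promoters.items()}, fh,
                      indent=1, default=_plain)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        gt = cls()
        for k, v in raw.items():
            v["stage_profile"] = tuple(v["stage_profile"])
            v["sl_sites"] = [tuple(s) for s in v["sl_sites"]]
            gt.promoters[k] = PlantedPromoter(**v)
        return gt


def default_archetypes() -> list[PromoterArchetype]:
    """The six promoter classes of the default synthetic study.

    Mirrors the field's canonical promoter taxonomy: broad maternal,
    zygotic and ubiquitous promoters; sharp adult/tissue-specific
    TATA-dependent promoters; sharp male-specific promoters driven by a
    TCTAGA element 44 bp upstream; and sharp ubiquitous promoters with
    an ACCATAA element.
    """
    return [
        PromoterArchetype("maternal_broad", "broad", None, 0,
                          (1.0, 0.8, 0.4, 0.1, 0.5, 0.05), 10.0),
        PromoterArchetype("zygotic_broad", "broad", None, 0,
                          (0.05, 1.0, 0.8, 0.3, 0.1, 0.05), 8.0),
        PromoterArchetype("ubiquitous_broad", "broad", None, 0,
                          (1.0, 1.0, 1.0, 1.0, 1.0, 1.0), 10.0),
        PromoterArchetype("adult_sharp_tata", "sharp", "TATAAA", 30,
                          (0.0, 0.0, 0.05, 0.3, 1.0, 0.8), 0.0),
        PromoterArchetype("male_sharp_tctaga", "sharp", "TCTAGA", 44,
                          (0.0, 0.0, 0.0, 0.0, 0.0, 1.0), 0.0),
        PromoterArchetype("ubiq_sharp_accataa", "sharp", "ACCATAA", 56,
                          (0.6, 0.6, 0.8, 1.0, 0.8, 0.8), 0.0),
    ]


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def generate_genome(
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    gc: float = 0.4,
    seed: int = 0,
    operon_fraction: float = 0.3,
    gene_len_range: tuple[int, int] = (600, 1800),
    intergenic_range: tuple[int, int] = (1600, 2600),
) -> tuple[Genome, pd.DataFrame]:
    """Generate a random genome with gene models, a fraction in operons.

    Genes are laid out as transcription units separated by intergenic
    gaps; a unit is either a single gene or an operon of 2-4 tightly
    spaced, co-oriented genes. The per-unit operon probability is chosen
    so the expected fraction of *genes* inside operons equals
    ``operon_fraction``.

    Returns the genome and a gene table with columns
    ``gene_id, chrom, start, end, strand, operon_id, operon_pos``
    (``operon_pos`` is 1 for an operon's 5'-most gene, 0 for
    monocistronic genes).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10,000 bp")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if not 0.0 <= operon_fraction < 1.0:
        raise ValueError("operon_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {
        f"chr{i + 1}": bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                                        size=chrom_len, p=probs))
        for i in range(n_chrom)
    }
    genome = Genome(seqs)

    # mean operon size is 3; solve p so that E[operon genes]/E[genes] = f
    p_op = operon_fraction / (3 - 2 * operon_fraction)
    rows = []
    op_counter = 0
    for chrom in genome:
        pos = 3000
        gidx = 0
        while True:
            is_operon = rng.random() < p_op
            size = int(rng.integers(2, 5)) if is_operon else 1
            lens = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size)
            span = int(lens.sum()) + 150 * (size - 1)
            if pos + span > chrom_len - 3000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            op_id = None
            if is_operon:
                op_counter += 1
                op_id = f"op{op_counter:04d}"
            starts = []
            cur = pos
            for ln in lens:
                starts.append((cur, cur + int(ln) - 1))
                cur += int(ln) + 150
            # transcription order: left-to-right on +, right-to-left on -
            order = range(size) if strand == "+" else range(size - 1, -1, -1)
            for k, j in enumerate(order, start=1):
                gidx += 1
                s, e = starts[j]
                rows.append({
                    "gene_id": f"{chrom}_g{gidx:04d}",
                    "chrom": chrom, "start": s, "end": e, "strand": strand,
                    "operon_id": op_id,
                    "operon_pos": k if is_operon else 0,
                })
            pos += span + int(rng.integers(*intergenic_range))
    genes = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return genome, genes


def _gene_tss(row) -> int:
    return int(row["start"]) if row["strand"] == "+" else int(row["end"])


# ---------------------------------------------------------------------------
# promoter planting
# ---------------------------------------------------------------------------

def plant_promoters(
    genome: Genome,
    genes: pd.DataFrame,
    archetypes: list[PromoterArchetype],
    n_per_archetype: int,
    seed: int = 0,
    internal_archetypes: tuple[str, ...] = (),
    tss_jitter: tuple[int, int] = (20, 120),
    retry: int = 50,
) -> GroundTruth:
    """Assign archetypes to genes, plant motifs into the genome, record truth.

    Each planted promoter is attached to a gene: its dominant TSS is
    placed a random distance upstream of the gene's annotated 5' end
    (or 30 bp inside the body for operon-internal promoters, i.e. genes
    with ``operon_pos >= 2`` when the archetype is listed in
    ``internal_archetypes``). Motifs are written into the reference so
    that the motif's 5' base sits exactly ``motif_offset`` bp upstream
    of the dominant TSS, strand-aware. Collisions with earlier edits are
    retried up to ``retry`` times, then raise :class:`PlacementError`.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    occupied: list[tuple[str, int, int]] = []

    def collides(chrom, a, b):
        return any(c == chrom and a <= e and b >= s for c, s, e in occupied)

    first_pool = genes[genes["operon_pos"] <= 1].index.to_list()
    internal_pool = genes[genes["operon_pos"] >= 2].index.to_list()

    pid = 0
    for arch in archetypes:
        pool = internal_pool if arch.id in internal_archetypes else first_pool
        if len(pool) < n_per_archetype:
            raise ValueError(
                f"not enough eligible genes for archetype {arch.id!r} "
                f"({len(pool)} < {n_per_archetype})")
        take = rng.choice(len(pool), size=n_per_archetype, replace=False)
        chosen = [pool[i] for i in sorted(take)]
        for i in sorted(take, reverse=True):
            del pool[i]
        for gi in chosen:
            g = genes.loc[gi]
            strand = g["strand"]
            sign = 1 if strand == "+" else -1
            anchor = _gene_tss(g)
            internal = g["operon_pos"] >= 2 and arch.id in internal_archetypes
            pid += 1
            for attempt in range(retry + 1):
                if internal:
                    tss = anchor + sign * 30
                else:
                    tss = anchor - sign * int(rng.integers(*tss_jitter))
                if arch.motif is None:
                    break
                pos5 = tss - sign * arch.motif_offset
                lo = min(pos5, pos5 + sign * (len(arch.motif) - 1))
                hi = max(pos5, pos5 + sign * (len(arch.motif) - 1))
                if not collides(g["chrom"], lo, hi):
                    break
            else:
                raise PlacementError(
                    f"could not place motif for {arch.id} at gene {g['gene_id']}")
            motif_start = None
            if arch.motif is not None:
                pos5 = tss - sign * arch.motif_offset
                s, e = genome.plant(g["chrom"], pos5, strand, arch.motif)
                occupied.append((g["chrom"], s, e))
                motif_start = pos5
            truth.add(PlantedPromoter(
                id=f"p{pid:04d}", archetype_id=arch.id, shape=arch.shape,
                chrom=g["chrom"], strand=strand, tss=tss,
                stage_profile=arch.stage_profile, spread_sd=arch.spread_sd,
                gene_id=g["gene_id"], operon_internal=internal,
                motif=arch.motif, motif_offset=arch.motif_offset,
                motif_start=motif_start,
            ))
    return truth


# ---------------------------------------------------------------------------
# CAGE tag simulation
# ---------------------------------------------------------------------------

#: Initiation pmf of sharp promoters: 94% at the dominant TSS, the rest
#: within +/-2 bp, so >=90% of tags fall within +/-2 bp of the truth.
_SHARP_OFFSETS = np.array([-2, -1, 0, 1, 2])
_SHARP_PROBS = np.array([0.01, 0.02, 0.94, 0.02, 0.01])


def _position_pmf(p: PlantedPromoter) -> tuple[np.ndarray, np.ndarray]:
    if p.shape == "sharp":
        return _SHARP_OFFSETS, _SHARP_PROBS
    sd = p.spread_sd
    offs = np.arange(-int(4 * sd), int(4 * sd) + 1)
    w = np.exp(-0.5 * (offs / sd) ** 2)
    return offs, w / w.sum()


def simulate_cage(
    genome: Genome,
    truth: GroundTruth,
    depth: int = 100_000,
    seed: int = 0,
    dispersion: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Emit per-stage CTSS count tables (chrom, pos, strand, count).

    Per stage, each promoter's expected share is its stage-profile
    weight times a gamma multiplier with mean 1 and variance
    ``dispersion`` (negative-binomial-style overdispersion); exactly
    ``depth`` tags are then drawn multinomially across all promoter
    positions, so per-stage totals equal the requested depth exactly.
    """
    if depth < 1000:
        raise ValueError("depth must be >= 1,000 tags per stage")
    rng = np.random.default_rng(seed)
    proms = list(truth.promoters.values())
    pmfs = [_position_pmf(p) for p in proms]

    tables: dict[str, pd.DataFrame] = {}
    for si, stage in enumerate(STAGES):
        weights = np.array([p.stage_profile[si] for p in proms], dtype=float)
        mult = rng.gamma(1.0 / dispersion, dispersion, size=len(proms))
        intensity = weights * mult
        chroms, positions, strands, probs = [], [], [], []
        for p, (offs, pp), w in zip(proms, pmfs, intensity):
            if w <= 0:
                continue
            sign = 1 if p.strand == "+" else -1
            pos = p.tss + sign * offs
            chroms.append(np.full(len(offs), p.chrom, dtype=object))
            positions.append(pos)
            strands.append(np.full(len(offs), p.strand, dtype=object))
            probs.append(w * pp)
        if not probs:
            tables[stage] = pd.DataFrame(
                columns=["chrom", "pos", "strand", "count"])
            continue
        prob = np.concatenate(probs)
        prob /= prob.sum()
        counts = rng.multinomial(depth, prob)
        df = pd.DataFrame({
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions).astype(int),
            "strand": np.concatenate(strands),
            "count": counts,
        })
        df = (df[df["count"] > 0]
              .groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
              .sort_values(["chrom", "strand", "pos"])
              .reset_index(drop=True))
        tables[stage] = df
    return tables


# ---------------------------------------------------------------------------
# SL trans-splice sites
# ---------------------------------------------------------------------------

def acceptor_ok(genome: Genome, chrom: str, pos: int, strand: str) -> bool:
    """True when the two bases immediately 5' of `pos` (strand-aware) are AG."""
    if strand == "+":
        return genome.fetch(chrom, pos - 2, pos - 1, "+") == "AG"
    return genome.fetch(chrom, pos + 1, pos + 2, "-") == "AG"


def simulate_sl_sites(
    genome: Genome,
    truth: GroundTruth,
    genes: pd.DataFrame,
    fraction_sl: float = 0.5,
    seed: int = 0,
    n_exclusion: int = 0,
    count_range: tuple[int, int] = (2, 20),
) -> pd.DataFrame:
    """Emit an SL trans-splice-site table and edit the genome accordingly.

    A fraction of genes receives one acceptor site just inside the gene
    body; an AG is written immediately upstream (strand-aware) so the
    acceptor-dinucleotide check passes by construction. Additionally,
    ``n_exclusion`` promoters carrying a planted TCTAGA get an acceptor
    whose AG coincides with motif positions 4-5 (the site sits at motif
    base 6), the configuration in which male transcription from the
    downstream TSS excludes the acceptor from the mRNA.

    Mutates ``genome`` (planted AGs) and ``truth`` (``sl_sites``,
    ``sl_exclusion``). Returns a table (chrom, pos, strand, count).
    """
    if not 0.0 <= fraction_sl <= 1.0:
        raise ValueError("fraction_sl must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []

    # exclusion subset: acceptor AG == TCTAGA positions 4-5
    candidates = [p for p in truth.promoters.values() if p.motif == "TCTAGA"]
    if n_exclusion > len(candidates):
        raise ValueError("n_exclusion exceeds number of TCTAGA promoters")
    excl_genes = set()
    idx = rng.choice(len(candidates), size=n_exclusion, replace=False)
    for i in sorted(idx):
        p = candidates[i]
        sign = 1 if p.strand == "+" else -1
        site = p.motif_start + sign * 5  # genomic position of motif base 6
        count = int(rng.integers(max(2, count_range[0]), count_range[1] + 1))
        rows.append((p.chrom, site, p.strand, count))
        p.sl_sites.append((p.chrom, site, p.strand, count))
        p.sl_exclusion = True
        excl_genes.add(p.gene_id)

    gene_to_prom = {p.gene_id: p for p in truth.promoters.values()}
    eligible = [i for i in genes.index if genes.loc[i, "gene_id"] not in excl_genes]
    n_sl = int(round(fraction_sl * len(eligible)))
    take = rng.choice(len(eligible), size=n_sl, replace=False)
    for i in sorted(take):
        g = genes.loc[eligible[i]]
        sign = 1 if g["strand"] == "+" else -1
        site = _gene_tss(g) + sign * 10
        genome.plant(g["chrom"], site - sign * 2, g["strand"], "AG")
        count = int(rng.integers(count_range[0], count_range[1] + 1))
        rows.append((g["chrom"], site, g["strand"], count))
        prom = gene_to_prom.get(g["gene_id"])
        if prom is not None:
            prom.sl_sites.append((g["chrom"], site, g["strand"], count))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# tiling array
# ---------------------------------------------------------------------------

def simulate_array(
    genome: Genome,
    truth: GroundTruth,
    probe_spacing: int = 50,
    seed: int = 0,
    amplitude: float = 0.5,
    period: float = 175.0,
    noise_sd: float = 0.1,
    dye_bias: float = 1.0,
    half_window: int = 500,
    baseline: float = 1000.0,
) -> pd.DataFrame:
    """Emit a two-channel probe table (chrom, pos, cy5, cy3).

    Around every broad promoter the true log2(Cy5/Cy3) follows a phased
    cosine of the given period with its trough at the TSS (ordered
    nucleosomes with a nucleosome-depleted region at initiation); sharp
    promoters and intergenic background are flat at zero. Gaussian noise
    and a global multiplicative dye bias are injected on the Cy5
    channel, so log2(Cy5/Cy3) = signal + noise + log2(dye_bias).
    """
    if probe_spacing < 1:
        raise ValueError("probe_spacing must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    broad = [p for p in truth.promoters.values() if p.shape == "broad"]
    for chrom in genome:
        pos = np.arange(probe_spacing, genome.length(chrom) + 1, probe_spacing)
        signal = np.zeros(len(pos), dtype=float)
        for p in broad:
            if p.chrom != chrom:
                continue
            d = (pos - p.tss) if p.strand == "+" else (p.tss - pos)
            m = np.abs(d) <= half_window
            signal[m] += -amplitude * np.cos(2 * np.pi * d[m] / period)
        noise = rng.normal(0.0, noise_sd, len(pos)) if noise_sd > 0 else 0.0
        cy5 = baseline * dye_bias * 2.0 ** (signal + noise)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "cy5": cy5,
            "cy3": np.full(len(pos), baseline),
        }))
    return pd.concat(frames, ignore_index=True)


def planted_nucleosome_profile(
    offsets: np.ndarray,
    amplitude: float = 0.5,
    period: float = 175.0,
    half_window: int = 500,
) -> np.ndarray:
    """The true metagene log2 ratio planted around broad promoters."""
    prof = -amplitude * np.cos(2 * np.pi * np.asarray(offsets, float) / period)
    prof[np.abs(offsets) > half_window] = 0.0
    return prof
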