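import numpy as np
import pandas as pd
import pytest

import promarch as pa


@pytest.fixture(scope="session")
def small_study():
    """A compact seeded synthetic study shared by read-only tests."""
    genome, genes = pa.generate_genome(n_chrom=2, chrom_len=150_000, seed=11)
    truth = pa.plant_promoters(
        genome, genes, pa.default_archetypes(), n_per_archetype=6, seed=12,
        internal_archetypes=("male_sharp_tctaga",))
    ctss = pa.simulate_cage(genome, truth, depth=100_000, seed=13)
    return {"genome": genome, "genes": genes, "truth": truth, "ctss": ctss}


@pytest.fixture()
def toy_genome():
    return pa.Genome({"chr1": "A" * 5000})


def make_ctss_table(positions, counts, chrom="chr1", strand="+", stage=None,
                    normalize=True):
    """Build a CTSS DataFrame (optionally tpm-normalised) from plain lists."""
    df = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=int),
        "strand": strand, "count": np.asarray(counts, dtype=int),
    }).sort_values("pos").reset_index(drop=True)
    df.attrs["stage"] = stage
    return pa.normalize_tpm(df) if normalize else df
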