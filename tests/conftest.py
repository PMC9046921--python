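import numpy as np
import pandas as pd
import pytest

from popscan.genotypes import GenotypeMatrix


def build_gm(
    dosages,
    pops,
    positions=None,
    chrom="s1",
    quals=None,
    depths=None,
    scaffold_len=None,
    samples=None,
):
    """Small-matrix construction helper for hand-built fixtures.

    ``dosages``: (n_samples, n_variants) with -1 for missing.
    ``pops``: population label per sample.
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_var = dosages.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if positions is None:
        positions = np.arange(1, n_var + 1) * 100
    if quals is None:
        quals = np.full(n_var, 50.0)
    chroms = [chrom] * n_var if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame({
        "chrom": chroms,
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": ["A"] * n_var,
        "alt": ["G"] * n_var,
        "qual": np.asarray(quals, dtype=float),
    })
    lengths = {}
    if scaffold_len is not None:
        for c in dict.fromkeys(chroms):
            lengths[c] = scaffold_len
    return GenotypeMatrix(
        samples=samples,
        pops={s: p for s, p in zip(samples, pops)},
        variants=variants,
        dosages=dosages,
        depths=None if depths is None else np.asarray(depths, dtype=np.int32),
        scaffold_lengths=lengths,
    )


@pytest.fixture
def two_pop_gm():
    """8-genotype table: pop A {AA, AA, Aa, aa}, pop B {aa, aa, Aa, AA}.

    Dosage counts the ALT ('a') allele: AA=0, Aa=1, aa=2.
    """
    dosages = np.array([[0], [0], [1], [2], [2], [2], [1], [0]])
    return build_gm(dosages, ["A"] * 4 + ["B"] * 4)
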