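import numpy as np
import pytest

import cosortpop as cp


@pytest.fixture(scope="session")
def small_genome():
    """30 kb annotated genome with genes on both strands."""
    return cp.make_genome(seed=11, length=30_000, gene_fraction=0.85)


@pytest.fixture(scope="session")
def small_population(small_genome):
    """20-haplotype population at moderate s/n SNP densities."""
    return cp.simulate_population(
        small_genome, n_haplotypes=20, target_ssnp_per_kb=3.0,
        target_nsnp_per_kb=2.0, seed=12,
    )


def random_dna(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def mutate_dna(seq: str, rate: float, seed: int) -> str:
    """Uniform random substitutions at the given per-base rate."""
    from cosortpop.io_formats import decode_seq, encode_seq

    rng = np.random.default_rng(seed)
    codes = encode_seq(seq).copy()
    hit = rng.random(len(codes)) < rate
    codes[hit] = (codes[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
    return decode_seq(codes)
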