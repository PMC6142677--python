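"""Species-clade delineation over a panel of synthetic genome bins.

Builds six genome bins with known relatedness (two two-member clades at ~2%
nucleotide divergence, one extension candidate sharing only ANI evidence,
and one unrelated bin), synthetic aligned 16S genes, and a ribosomal-
protein-style tree, then runs the three evidence channels and the 2-of-3
rule with ANI-only extension.

Writes results/clade_assignments.tsv and results/clade_evidence.tsv.
"""

import argparse
import itertools
import pathlib
import tempfile

import numpy as np
import pandas as pd

import cosortpop as cp
from cosortpop.clade_delineation import CladeEvidence, Criterion

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def _random_dna(length, rng):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _mutate(seq, rate, rng):
    from cosortpop.io_formats import decode_seq, encode_seq

    codes = encode_seq(seq).copy()
    hit = rng.random(len(codes)) < rate
    codes[hit] = (codes[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
    return decode_seq(codes)


def main(seed: int = 1) -> cp.CladeAssignment:
    rng = np.random.default_rng(seed + 60)
    base1 = _random_dna(60_000, rng)
    base2 = _random_dna(60_000, rng)
    genomes = {
        "binA": base1,
        "binB": _mutate(base1, 0.02, rng),            # clade with A
        "binE": _mutate(base1, 0.03, rng),            # extension candidate
        "binC": base2,
        "binD": _mutate(base2, 0.02, rng),            # clade with C
        "binF": _random_dna(60_000, rng),             # unrelated
    }
    s16_base1 = _random_dna(1200, rng)
    s16_base2 = _random_dna(1200, rng)
    s16 = {
        "binA": s16_base1,
        "binB": _mutate(s16_base1, 0.01, rng),        # ~99% to A
        "binC": s16_base2,
        "binD": _mutate(s16_base2, 0.012, rng),       # ~98.8% to C
        # binE and binF assemblies carry no 16S gene (missing evidence)
    }
    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
        fh.write("(((binA:0.01,binB:0.01):0.2,(binC:0.01,binD:0.01):0.2):0.1,"
                 "binF:0.4);")
        tree_path = fh.name
    tree = cp.read_newick(tree_path)

    evidence = []
    for a, b in itertools.combinations(sorted(genomes), 2):
        ani, aligned = cp.anib(genomes[a], genomes[b])
        ident = (cp.pairwise_16s_identity(s16[a], s16[b])
                 if a in s16 and b in s16 else None)
        rel = cp.tree_criterion(tree, [a, b])
        evidence.append(CladeEvidence(
            a, b, s16_identity=ident, ani_value=ani, ani_aligned_length=aligned,
            tree_relation=rel if rel != Criterion.MISSING else None))

    assignment = cp.delineate_clades(evidence, sorted(genomes))

    RESULTS.mkdir(exist_ok=True)
    ev_rows = []
    for ev in evidence:
        st = cp.evaluate_pair(ev)
        ev_rows.append({
            "id_a": ev.id_a, "id_b": ev.id_b,
            "s16_identity": "" if ev.s16_identity is None else f"{ev.s16_identity:.2f}",
            "ani": "" if ev.ani_value is None else f"{ev.ani_value:.2f}",
            "ani_aligned_bp": ev.ani_aligned_length,
            "s16": st["s16"].value, "ani_criterion": st["ani"].value,
            "tree": st["tree"].value,
        })
    pd.DataFrame(ev_rows).to_csv(RESULTS / "clade_evidence.tsv", sep="\t", index=False)
    out = pd.DataFrame(
        [{"genome_id": g, "clade": c} for g, c in sorted(assignment.assignments.items())]
    )
    out.to_csv(RESULTS / "clade_assignments.tsv", sep="\t", index=False)

    print(pd.DataFrame(ev_rows).to_string(index=False))
    print()
    print(out.to_string(index=False))
    print("\nTwo species-level clades recovered; the extension candidate joins "
          "on ANI alone (its missing 16S is tolerated, conflicts are not); the "
          "unrelated bin stays unassigned.")
    return assignment


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
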